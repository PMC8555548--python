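import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import polyterm as pt
from polyterm import annotation, readthrough as rt

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_ds() -> pt.SynthDataset:
    """The default synthetic dataset used by recovery tests."""
    return pt.generate(pt.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_features(default_ds):
    return annotation.derive_features(default_ds.models,
                                      default_ds.genome.lengths())


@pytest.fixture(scope="session")
def pipeline_results(default_ds):
    """Collapse -> readthrough -> classify -> differential on the default set."""
    ds = default_ds
    usage = (ds.counts[ds.counts["sample"].isin(ds.wt_samples)]
             .groupby("pas_id")["up"].mean().to_dict())
    sites = rt.collapse_pas(ds.pas_sites, usage)
    cdf = ds.counts[ds.counts.pas_id.isin({s.pas_id for s in sites})]
    table = rt.readthrough_table(cdf)
    expr = {pid: ds.expression[ds.pas_gene[pid]] for pid in table.index}
    wt_down = cdf.pivot(index="pas_id", columns="sample", values="down")
    cats = rt.classify_pas(table, ds.wt_samples, expr, wt_down=wt_down)
    analyzable = cats[cats == "analyzable"].index
    diff = rt.differential(table.loc[table.index.isin(analyzable)],
                           ds.mutant_samples, ds.wt_samples)
    return {"sites": sites, "table": table, "categories": cats, "diff": diff}
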