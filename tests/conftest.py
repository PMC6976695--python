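import numpy as np
import pandas as pd
import pytest

import picodepth as pk


@pytest.fixture
def tiny_table():
    """3 OTUs x 2 samples with simple integer counts."""
    return pk.OtuTable(
        pd.DataFrame(
            {"s1": [6, 0, 2], "s2": [2, 2, 0]},
            index=["otu1", "otu2", "otu3"],
        )
    )


def _make_meta(sample_id, station, depth, layer, template, oxygen=6.0, dsl=False,
               ocean="Atlantic", light=None):
    return pk.SampleInfo(
        sample_id=sample_id,
        station=station,
        depth_m=depth,
        layer=layer,
        ocean=ocean,
        template=template,
        temperature_C=15.0,
        salinity=35.0,
        oxygen_mg_L=oxygen,
        light=(layer in ("surface", "DCM")) if light is None else light,
        dsl=dsl,
        sublayer=pk.LayerBounds().sublayer(layer, depth),
        omz=oxygen < 2.0,
    )


@pytest.fixture
def make_sample_info():
    return _make_meta


@pytest.fixture(scope="session")
def small_sim():
    """4-station, reduced-size paired simulation used across modules."""
    design, meta = pk.make_design(
        n_stations=4,
        seed=7,
        reads_per_sample=5_000,
        n_otus_per_group={g: 10 for g in pk.synthetic.DEFAULT_GROUPS},
    )
    rdna, rrna, tax, truth = pk.simulate_tables(design, pk.default_truth(7))
    return {
        "design": design,
        "meta": meta,
        "rdna": rdna,
        "rrna": rrna,
        "tax": tax,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_sim():
    """Full default design (13 stations x 7 depths), one seed."""
    design, meta = pk.make_design(seed=11)
    rdna, rrna, tax, truth = pk.simulate_tables(design, pk.default_truth(11))
    return {
        "design": design,
        "meta": meta,
        "rdna": rdna,
        "rrna": rrna,
        "tax": tax,
        "truth": truth,
    }
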