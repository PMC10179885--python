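"""Shared fixtures: compositions and simulated runs reused across tests.

Heavy simulations are session-scoped; everything is generated in memory
from the packaged tables, so the suite needs no external data.
"""

import pytest

import argentms as am


@pytest.fixture(scope="session")
def table4():
    return am.load_fixture("table4")


@pytest.fixture(scope="session")
def table3():
    return am.load_fixture("table3")


@pytest.fixture(scope="session")
def comp_t4(table4):
    return am.composition_from_report(list(table4.rows), table4.class_shares)


@pytest.fixture(scope="session")
def run_t4_clean(comp_t4):
    """Noiseless, jitter-free simulation of the cockroach profile."""
    return am.simulate_run(comp_t4, noise_sd=0.0, rt_jitter=0.0, seed=11)


@pytest.fixture(scope="session")
def result_t4_clean(run_t4_clean):
    return am.annotate_run(run_t4_clean)


@pytest.fixture(scope="session")
def standards_comp():
    """Fig 4-style synthetic standards: three cis/trans monoene pairs."""
    rows = []
    num = 1
    for cn, cis_area, trans_area in [(26, 9.0, 20.0), (32, 16.0, 36.0), (38, 5.0, 14.0)]:
        rows.append((cn, cis_area, ("cis",)))
        rows.append((cn, trans_area, ("trans",)))
        num += 2
    model = am.RetentionModel.default()
    entries = []
    total_cis = sum(a for _, a, g in rows if g == ("cis",))
    total_trans = sum(a for _, a, g in rows if g == ("trans",))
    total = total_cis + total_trans
    for cn, area, geom in rows:
        sp = am.HydrocarbonSpecies(cn, 1, geometry=geom)
        rt = am.predict_rt(sp, model, "III", 15)
        from argentms.simulate import GroundTruthComposition, GroundTruthEntry

        entries.append(
            GroundTruthEntry(
                species=sp, rt=rt, abundance_pct=100.0 * area / total,
                class_share_pct=100.0,
            )
        )
    from argentms.simulate import GroundTruthComposition

    return GroundTruthComposition(entries=tuple(entries), class_shares={1: 100.0})


@pytest.fixture(scope="session")
def run_standards(standards_comp):
    return am.simulate_run(standards_comp, noise_sd=0.0, rt_jitter=0.0, seed=5)
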