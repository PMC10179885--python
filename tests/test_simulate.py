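"""Simulator: gradient, retention, adduct response, rendering, mzML."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import argentms as am
from argentms.chem import MASS_C13_DELTA, ion_mz
from argentms.simulate import (
    _FRAGMENT_MZ,
    GroundTruthComposition,
    GroundTruthEntry,
    ResponseModel,
)


class TestGradient:
    @pytest.mark.parametrize("t,expected", [(0, 0.0), (10, 5.0), (300, 100.0)])
    def test_linear_ramp_with_clipping(self, t, expected):
        prog = am.GradientProgram("III", 0.0, 0.5, 140.0)
        assert am.gradient_percent_B(t, prog) == expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            am.gradient_percent_B(-1.0, am.GradientProgram())

    @given(st.floats(min_value=0, max_value=1000))
    @settings(derandomize=True)
    def test_percent_b_bounded(self, t):
        prog = am.GradientProgram("III", 10.0, 0.75, 140.0)
        assert 0.0 <= am.gradient_percent_B(t, prog) <= 100.0


@pytest.fixture(scope="module")
def model():
    return am.RetentionModel.default()


class TestRetention:
    def test_saturated_window(self, model):
        rt = am.predict_rt(am.HydrocarbonSpecies(30, 0), model, "III", 15)
        assert 6.4 <= rt <= 6.6

    def test_trans_before_cis(self, model):
        for db in (1, 2, 3):
            cis = am.HydrocarbonSpecies(40, db, geometry=("cis",) * db)
            trans = am.HydrocarbonSpecies(40, db, geometry=("trans",) * db)
            assert am.predict_rt(trans, model, "III", 15) < am.predict_rt(
                cis, model, "III", 15
            )

    def test_heavier_chain_elutes_earlier(self, model):
        rt41 = am.predict_rt(am.HydrocarbonSpecies(41, 2), model, "III", 15)
        rt43 = am.predict_rt(am.HydrocarbonSpecies(43, 2), model, "III", 15)
        assert rt43 < rt41

    def test_class_order_strict(self, model):
        rts = [
            am.predict_rt(am.HydrocarbonSpecies(40, db), model, "III", 15)
            for db in (0, 1, 2, 3)
        ]
        assert rts == sorted(rts) and len(set(rts)) == 4

    def test_unknown_condition_rejected(self, model):
        with pytest.raises(KeyError):
            am.predict_rt(am.HydrocarbonSpecies(30, 0), model, "III", 20)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            am.RetentionModel(
                class_apex={("III", 15.0): {0: 6.5}}, cn_slope={0: 0.01, 1: -1, 2: -1, 3: -1}
            )


class TestAdductProfile:
    @given(
        st.integers(min_value=0, max_value=3),
        st.floats(min_value=0, max_value=100),
        st.sampled_from(["I", "II", "III"]),
    )
    @settings(derandomize=True)
    def test_fractions_sum_to_one(self, db, pct, system):
        prof = am.adduct_profile(db, pct, system)
        assert sum(prof.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in prof.values())

    @given(st.floats(min_value=0, max_value=100))
    @settings(derandomize=True)
    def test_saturated_dominated_by_deprotonated(self, pct):
        prof = am.adduct_profile(0, pct, "III")
        assert prof["[M-H]+"] == max(prof.values())

    def test_protonated_peaks_at_midrange_toluene(self):
        at0 = am.adduct_profile(1, 0.0)["[M+H]+"]
        at50 = am.adduct_profile(1, 50.0)["[M+H]+"]
        at100 = am.adduct_profile(1, 100.0)["[M+H]+"]
        assert at50 >= at0 and at50 >= at100

    def test_polyunsaturated_gain_radical_and_toluene_adducts(self):
        low = am.adduct_profile(2, 10.0)
        high = am.adduct_profile(2, 90.0)
        assert high["[M]+."] > low["[M]+."]
        assert high["[M+C7H9]+"] > low["[M+C7H9]+"]
        assert "[M+C7H9]+" not in am.adduct_profile(1, 90.0)

    def test_isooctane_system_gives_butyl_adduct(self):
        prof = am.adduct_profile(1, 50.0, "II")
        assert prof["[M+C4H9]+"] == max(prof.values())

    def test_out_of_range_percentage_rejected(self):
        with pytest.raises(ValueError):
            am.adduct_profile(1, 101.0)


class TestComposition:
    def test_cockroach_profile_yields_44_entries(self, comp_t4):
        assert len(comp_t4) == 44
        assert not comp_t4.trace_entries

    def test_no_ratio_no_traces(self, table3):
        comp = am.composition_from_report(
            list(table3.rows), table3.class_shares, cis_trans_ratio=None
        )
        assert len(comp.trace_entries) == 0 and len(comp) == 136

    def test_trans_traces_at_configured_ratio(self, table3):
        comp = am.composition_from_report(
            list(table3.rows), table3.class_shares, cis_trans_ratio=1000.0
        )
        cis = sum(
            e.abundance_pct * e.class_share_pct
            for e in comp.entries
            if e.species.all_cis
        )
        trans = sum(
            e.abundance_pct * e.class_share_pct
            for e in comp.entries
            if e.species.all_trans
        )
        assert cis / trans == pytest.approx(1000.0, abs=1.0)
        for e in comp.trace_entries:
            mate = next(
                c
                for c in comp.main_entries
                if c.species.carbon_number == e.species.carbon_number
                and c.species.double_bonds == e.species.double_bonds
                and c.isomer_index == e.isomer_index
            )
            assert e.rt < mate.rt

    def test_missing_class_share_rejected(self, table4):
        with pytest.raises(ValueError, match="share"):
            am.composition_from_report(list(table4.rows), {0: 100.0})

    def test_tsv_round_trip(self, comp_t4, tmp_path):
        p = comp_t4.to_tsv(tmp_path / "truth.tsv")
        back = GroundTruthComposition.from_tsv(p)
        assert len(back) == len(comp_t4)
        assert back.entries[0].species == comp_t4.entries[0].species
        assert back.entries[-1].rt == pytest.approx(comp_t4.entries[-1].rt)


def _species_total_area(run, species, rt):
    """Integrated current over the adduct channels one species actually
    produces in the hexane/toluene system, inside a window around its peak.

    The m/z window is very tight and the integration is time-restricted so
    the measurement is immune to genuine channel aliasing (e.g. the
    [M+C4H9]+ ion of CN:0 is the *same ion formula* as [M+H]+ of (CN+4):0,
    and [M+C3H3]+ of CN:1 equals [M-H]+ of (CN+3):2); the annotation
    pipeline has to cope with those, but they would blur a conservation
    measurement."""
    adducts = tuple(am.adduct_profile(species.double_bonds, 50.0, "III"))
    eic = am.extract_eic(run, species, adducts, tolerance=1e-4)
    eic = eic.restricted(rt - 1.5, rt + 1.5)
    return float(np.trapezoid(eic.intensity, eic.rt))


class TestSimulation:
    def test_determinism_same_seed(self, comp_t4):
        kw = dict(noise_sd=0.05, scan_rate=2.0, seed=123)
        r1 = am.simulate_run(comp_t4, **kw)
        r2 = am.simulate_run(comp_t4, **kw)
        assert len(r1) == len(r2)
        for a, b in zip(r1.scans, r2.scans):
            assert a.rt == b.rt
            assert np.array_equal(a.mz, b.mz)
            assert np.array_equal(a.intensity, b.intensity)

    def test_different_seed_differs(self, comp_t4):
        r1 = am.simulate_run(comp_t4, seed=1)
        r2 = am.simulate_run(comp_t4, seed=2)
        assert any(
            not np.array_equal(a.intensity, b.intensity)
            for a, b in zip(r1.scans, r2.scans)
        )

    def test_single_species_conservation(self):
        sp = am.HydrocarbonSpecies(32, 1, geometry=("cis",))
        model = am.RetentionModel.default()
        entry = GroundTruthEntry(
            species=sp, rt=am.predict_rt(sp, model), abundance_pct=100.0,
            class_share_pct=100.0,
        )
        comp = GroundTruthComposition(entries=(entry,), class_shares={1: 100.0})
        response = ResponseModel(fragment_floor=0.0)
        run = am.simulate_run(
            comp, response=response, noise_sd=0.0, rt_jitter=0.0, seed=0
        )
        area = _species_total_area(run, sp, entry.rt)
        expected = 100.0 * 100.0 * response.db_response[1]
        assert area == pytest.approx(expected, rel=0.01)

    def test_cross_species_conservation(self, run_t4_clean, comp_t4):
        """area / (abundance * share * response) constant across species."""
        resp = ResponseModel().db_response
        ratios = []
        for e in comp_t4.entries:
            if (e.species.carbon_number, e.species.double_bonds) in ((27, 1), (40, 1)):
                continue  # isomer families share one EIC; skip in this check
            if e.species.carbon_number > 61:
                continue  # [M+C3H3]+ falls beyond the m/z 900 scan limit
            area = _species_total_area(run_t4_clean, e.species, e.rt)
            ratios.append(
                area
                / (e.abundance_pct * e.class_share_pct * resp[e.species.double_bonds])
            )
        ratios = np.array(ratios)
        assert ratios.std() / ratios.mean() < 0.01

    def test_scan_times_strictly_increasing(self, run_t4_clean):
        t = run_t4_clean.scan_times
        assert np.all(np.diff(t) > 0)

    def test_all_mz_within_configured_range(self, run_t4_clean):
        lo, hi = run_t4_clean.metadata["mz_range"]
        for s in run_t4_clean.scans:
            if len(s.mz):
                assert s.mz.min() >= lo and s.mz.max() <= hi

    def test_emitted_mz_are_expected_channels(self, run_t4_clean, comp_t4):
        expected = []
        for e in comp_t4.entries:
            for name in am.ADDUCT_REGISTRY:
                base = ion_mz(e.species, name, "monoisotopic")
                expected.extend(base + k * MASS_C13_DELTA for k in range(3))
        expected.extend(_FRAGMENT_MZ)
        expected = np.unique(np.array(expected))
        for s in run_t4_clean.scans:
            if not len(s.mz):
                continue
            idx = np.clip(np.searchsorted(expected, s.mz), 1, len(expected) - 1)
            nearest = np.minimum(
                np.abs(s.mz - expected[idx - 1]), np.abs(s.mz - expected[idx])
            )
            assert nearest.max(initial=0.0) < 1e-6

    def test_diene_apex_at_calibrated_time(self, table3):
        """The most intense diunsaturated channel apexes at the configured
        class apex (74.1 min for the hexane/toluene system at 15 degC)."""
        comp = am.composition_from_report(list(table3.rows), table3.class_shares)
        run = am.simulate_run(comp, noise_sd=0.0, rt_jitter=0.0, seed=2)
        best, best_apex = 0.0, None
        for cn in range(37, 47):
            eic = am.extract_eic(run, am.HydrocarbonSpecies(cn, 2))
            i = int(np.argmax(eic.intensity))
            if eic.intensity[i] > best:
                best, best_apex = float(eic.intensity[i]), float(eic.rt[i])
        assert best_apex == pytest.approx(74.1, abs=1.0)

    def test_out_of_window_species_truncated_with_warning(self, comp_t4):
        with pytest.warns(UserWarning, match="truncated"):
            run = am.simulate_run(
                comp_t4, noise_sd=0.0, rt_jitter=0.0, seed=0, duration=40.0
            )
        assert len(run.metadata["truncated"]) == 6  # dienes and trienes cut
        assert run.duration == 40.0

    def test_order_properties_in_ground_truth(self, table3):
        comp = am.composition_from_report(
            list(table3.rows), table3.class_shares, cis_trans_ratio=1000.0
        )
        apex_by_class = {}
        for e in comp.main_entries:
            db = e.species.double_bonds
            cur = apex_by_class.get(db)
            if cur is None or e.abundance_pct > cur[0]:
                apex_by_class[db] = (e.abundance_pct, e.rt)
        rts = [apex_by_class[db][1] for db in (0, 1, 2, 3)]
        assert rts == sorted(rts)
        # within a class, among single-isomer families (no positional
        # sub-peak offsets), Rt strictly decreases with CN
        fam_sizes = {}
        for e in comp.main_entries:
            key = (e.species.carbon_number, e.species.double_bonds)
            fam_sizes[key] = fam_sizes.get(key, 0) + 1
        singles = {}
        for e in comp.main_entries:
            key = (e.species.carbon_number, e.species.double_bonds)
            if fam_sizes[key] == 1:
                singles.setdefault(e.species.double_bonds, []).append(e)
        checked = 0
        for group in singles.values():
            group = sorted(group, key=lambda x: x.species.carbon_number)
            for a, b in zip(group, group[1:]):
                assert a.rt > b.rt
                checked += 1
        assert checked > 5


class TestMzml:
    def test_empty_run_round_trip(self, tmp_path):
        run = am.SyntheticRun(scans=[], metadata={})
        p = am.write_mzml(run, tmp_path / "empty.mzml")
        back = am.read_mzml(p)
        assert len(back) == 0

    def test_small_run_round_trip_bitfaithful(self, run_standards, tmp_path):
        run = am.SyntheticRun(
            scans=[s for s in run_standards.scans if len(s.mz)][:10],
            metadata=dict(run_standards.metadata),
        )
        p = am.write_mzml(run, tmp_path / "ten.mzml")
        back = am.read_mzml(p)
        assert len(back) == 10
        assert np.all(np.diff(back.scan_times) > 0)
        for a, b in zip(run.scans, back.scans):
            assert b.rt == a.rt
            assert np.array_equal(a.mz, b.mz)
            assert np.array_equal(a.intensity, b.intensity)

    def test_independent_reader_agrees(self, run_standards, tmp_path):
        """Bioconductor mzR (an unrelated C++ mzML implementation) must
        recover the same scan count, Rt values and peak lists."""
        run = am.SyntheticRun(
            scans=[s for s in run_standards.scans if len(s.mz)][:5],
            metadata=dict(run_standards.metadata),
        )
        p = am.write_mzml(run, tmp_path / "xreader.mzml")
        script = (
            'suppressMessages(library(mzR));'
            f'f <- openMSfile("{p}"); h <- header(f);'
            'cat(nrow(h), "\\n");'
            'cat(sprintf("%.8f", h$retentionTime), sep="\\n");'
            'for (i in seq_len(nrow(h))) {'
            '  pk <- peaks(f, i);'
            '  cat(sprintf("%.6f:%.6f", pk[,1], pk[,2]), sep="\\n")'
            '}'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.splitlines()
        assert int(out[0]) == 5
        rts = [float(v) for v in out[1 : 6]]  # mzR reports seconds
        for got, scan in zip(rts, run.scans):
            assert got == pytest.approx(scan.rt * 60.0, abs=1e-4)
        pairs = [tuple(map(float, line.split(":"))) for line in out[6:]]
        expected = [
            (m, i) for s in run.scans for m, i in zip(s.mz, s.intensity)
        ]
        assert len(pairs) == len(expected)
        for (gm, gi), (em, ei) in zip(pairs, expected):
            assert gm == pytest.approx(em, abs=1e-5)
            assert gi == pytest.approx(ei, rel=1e-5)
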