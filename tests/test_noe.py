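"""NOE forward model, restraint tables, averages and violations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from noeme.noe import (
    CLASS_DISTANCES_ANGSTROM,
    NOERestraint,
    RestraintSet,
    build_signal_matrix,
    count_violations,
    forward_signal,
    load_critical_panel,
    relative_signals,
    violation_report,
    violation_score,
)
from noeme.structures import Ensemble, proton_distance
from noeme.synthetic import StateSpec, default_pair_panel, generate_toy_ensemble


@pytest.fixture(scope="module")
def small_ensemble():
    ens, _ = generate_toy_ensemble(
        5, [StateSpec("s", 1.0, syn_residues=(3,))], 4, seed=9
    )
    return ens


class TestForwardSignal:
    def test_one_nanometer(self):
        assert forward_signal(10.0) == pytest.approx(1.0)

    def test_strong_threshold(self):
        # 3.6 A = 0.36 nm; cross-check in log space
        expect = math.exp(-6.0 * math.log(0.36))
        assert forward_signal(3.6) == pytest.approx(expect, rel=1e-12)

    def test_angstrom_nm_scale_consistency(self):
        # f in nm^-6 equals f in A^-6 rescaled by 10^6 per length decade
        for d in (2.5, 3.6, 5.0, 6.5):
            assert forward_signal(d) == pytest.approx(d**-6 * 1e6, rel=1e-12)

    @given(st.floats(min_value=1.0, max_value=20.0), st.floats(min_value=0.01, max_value=5.0))
    def test_monotonically_decreasing(self, d, delta):
        assert forward_signal(d) > forward_signal(d + delta)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            forward_signal(0.0)
        with pytest.raises(ValueError):
            forward_signal(-1.0)


class TestRestraintSet:
    def test_class_distance_map(self):
        assert CLASS_DISTANCES_ANGSTROM == {"strong": 3.6, "medium": 5.0, "weak": 6.5}
        for cls, d in CLASS_DISTANCES_ANGSTROM.items():
            r = NOERestraint(1, "H8", 2, "H1'", d_exp=d, signal_class=cls)
            assert r.f_exp == pytest.approx(forward_signal(d))

    def test_csv_roundtrip_and_aliases(self, tmp_path):
        df = pd.DataFrame(
            {
                "res_i": [1, 2, 3],
                "atom_i": ["H8", "H6", "H1′"],
                "res_j": [2, 3, 4],
                "atom_j": ["H1'", "H1'", "H6"],
                "class": ["s", "m", "l"],
            }
        )
        path = tmp_path / "r.csv"
        df.to_csv(path, index=False)
        rs = RestraintSet.from_csv(path)
        assert [r.d_exp for r in rs] == [3.6, 5.0, 6.5]
        assert rs[0].atom_j == "H1'"
        assert rs[2].atom_i == "H1'"  # unicode prime normalized
        back = tmp_path / "out.csv"
        rs.to_csv(back)
        rs2 = RestraintSet.from_csv(back)
        assert [r.d_exp for r in rs2] == [r.d_exp for r in rs]

    def test_explicit_dmax_and_ignored_dmin(self, tmp_path, caplog):
        df = pd.DataFrame(
            {
                "res_i": [1], "atom_i": ["H8"], "res_j": [2], "atom_j": ["H1'"],
                "d_max": [4.2], "d_min": [1.8],
            }
        )
        path = tmp_path / "r.csv"
        df.to_csv(path, index=False)
        import logging

        with caplog.at_level(logging.INFO, logger="noeme.noe"):
            rs = RestraintSet.from_csv(path)
        assert rs[0].d_exp == pytest.approx(4.2)
        assert any("minimum distances" in m for m in caplog.messages)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="res_i"):
            RestraintSet.from_dataframe(pd.DataFrame({"foo": [1]}))

    def test_bundled_critical_panel(self):
        panel = load_critical_panel()
        assert len(panel) == 23
        classes = [r.signal_class for r in panel]
        assert classes.count("strong") == 2
        assert classes.count("weak") == 2
        assert classes.count("medium") == 19
        shifted = load_critical_panel(residue_offset=63)
        assert shifted[0].res_i == panel[0].res_i + 63


class TestSignalMatrix:
    def test_single_entry(self, small_ensemble):
        rs = RestraintSet([NOERestraint(1, "H1'", 3, "H8", d_exp=5.0)])
        ens1 = Ensemble([small_ensemble[0]])
        mat = build_signal_matrix(ens1, rs)
        d = proton_distance(small_ensemble[0], ((1, "H1'"), (3, "H8")))
        assert mat.shape == (1, 1)
        assert mat[0, 0] == pytest.approx(forward_signal(d))

    def test_snapshot_permutation_permutes_columns(self, small_ensemble):
        rs = RestraintSet([NOERestraint(1, "H1'", 3, "H8", d_exp=5.0),
                           NOERestraint(2, "H6", 4, "H1'", d_exp=3.6)])
        mat = build_signal_matrix(small_ensemble, rs)
        perm = [2, 0, 3, 1]
        permuted = Ensemble([small_ensemble[i] for i in perm])
        mat2 = build_signal_matrix(permuted, rs)
        assert np.allclose(mat2, mat[:, perm])

    def test_elementwise_bruteforce(self, small_ensemble):
        pairs = default_pair_panel(5)[:3]
        rs = RestraintSet(
            [NOERestraint(ri, ai, rj, aj, d_exp=5.0) for ri, ai, rj, aj in pairs]
        )
        mat = build_signal_matrix(small_ensemble, rs)
        for i, r in enumerate(rs):
            for t, snap in enumerate(small_ensemble):
                d = proton_distance(snap, r.pair)
                assert mat[i, t] == pytest.approx((d / 10.0) ** -6, rel=1e-12)

    def test_unresolvable_pair_names_restraint(self, small_ensemble):
        rs = RestraintSet([NOERestraint(1, "H1'", 2, "H77", d_exp=5.0)])
        with pytest.raises(KeyError, match="restraint 1"):
            build_signal_matrix(small_ensemble, rs)


class TestRelativeSignals:
    def test_exact_thresholds_give_unit_ratios(self, small_ensemble):
        # set every d_exp to the measured distance of snapshot 0
        pairs = default_pair_panel(5)
        rs = RestraintSet(
            [
                NOERestraint(ri, ai, rj, aj,
                             d_exp=proton_distance(small_ensemble[0], ((ri, ai), (rj, aj))))
                for ri, ai, rj, aj in pairs
            ]
        )
        mat = build_signal_matrix(Ensemble([small_ensemble[0]]), rs)
        ratios = relative_signals(mat, rs)
        assert np.allclose(ratios, 1.0, atol=1e-10)

    def test_weighted_mean_oracle(self, small_ensemble, rng):
        rs = RestraintSet([NOERestraint(1, "H1'", 3, "H8", d_exp=5.0),
                           NOERestraint(2, "H6", 5, "H1'", d_exp=3.6)])
        mat = build_signal_matrix(small_ensemble, rs)
        w = rng.random(len(small_ensemble))
        w = w / w.sum()
        ratios = relative_signals(mat, rs, w)
        for i in range(len(rs)):
            brute = sum(w[t] * mat[i, t] for t in range(mat.shape[1]))
            assert ratios[i] == pytest.approx(brute / rs[i].f_exp, rel=1e-12)

    def test_one_hot_weights_pick_single_snapshot(self, small_ensemble):
        rs = RestraintSet([NOERestraint(1, "H1'", 3, "H8", d_exp=5.0)])
        mat = build_signal_matrix(small_ensemble, rs)
        w = np.zeros(len(small_ensemble))
        w[2] = 1.0
        ratios = relative_signals(mat, rs, w)
        assert ratios[0] == pytest.approx(mat[0, 2] / rs[0].f_exp)

    def test_average_bounded_by_extremes(self, small_ensemble, rng):
        rs = RestraintSet([NOERestraint(2, "H6", 4, "H1'", d_exp=5.0)])
        mat = build_signal_matrix(small_ensemble, rs)
        w = rng.random(len(small_ensemble))
        ratios = relative_signals(mat, rs, w / w.sum())
        avg = ratios[0] * rs[0].f_exp
        assert mat[0].min() - 1e-12 <= avg <= mat[0].max() + 1e-12


class TestViolations:
    def test_no_violations(self):
        assert count_violations(np.array([1.0, 1.5, 2.0])) == 0

    def test_counting_is_strict(self):
        assert count_violations(np.array([0.5, 1.0, 2.0])) == 1

    def test_score_shortfall(self):
        assert violation_score(np.array([0.5, 2.0])) == pytest.approx(0.5)
        assert violation_score(np.array([1.0, 1.2])) == 0.0

    def test_score_monotone_in_satisfied_restraints(self, rng):
        ratios = rng.random(6) * 2
        base = violation_score(ratios)
        extended = violation_score(np.append(ratios, 1.7))
        assert extended == pytest.approx(base)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            violation_score(np.array([1.0]), mode="bogus")

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            count_violations(np.array([np.nan]))

    def test_report_critical_filter_is_superset_of_violations(self, small_ensemble):
        pairs = default_pair_panel(5)
        rs = RestraintSet(
            [NOERestraint(ri, ai, rj, aj, d_exp=4.0) for ri, ai, rj, aj in pairs]
        )
        mat = build_signal_matrix(small_ensemble, rs)
        ratios = relative_signals(mat, rs)
        full = violation_report(rs, ratios)
        critical = violation_report(rs, ratios, critical_below=1.2)
        violated = set(full[full.violated].restraint)
        assert violated <= set(critical.restraint)
        assert (critical.relative_signal < 1.2).all()
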