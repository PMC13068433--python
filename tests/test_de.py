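import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from trapdiff import (DEThresholds, GroupDesign, TranslatomeDE,
                      bhattacharyya_modified, call_de, dual_flashlight_table,
                      log2_fold_change, marker_enrichment, ssmd)
from trapdiff.de import bhattacharyya_coefficient_gaussian

from conftest import make_matrix


def bc_by_numerical_integration(mu_a, sd_a, mu_b, sd_b):
    """Independent oracle: ∫ sqrt(p_a · p_b) dx by quadrature."""
    lo = min(mu_a - 10 * sd_a, mu_b - 10 * sd_b)
    hi = max(mu_a + 10 * sd_a, mu_b + 10 * sd_b)
    val, _ = quad(lambda x: np.sqrt(norm.pdf(x, mu_a, sd_a) * norm.pdf(x, mu_b, sd_b)),
                  lo, hi, limit=200)
    return val


class TestLog2FoldChange:
    def test_doubling(self):
        assert log2_fold_change([4, 4, 4], [2, 2, 2], 0) == pytest.approx(1.0)

    def test_identity(self):
        assert log2_fold_change([1, 2, 3], [1, 2, 3], 0.01) == 0.0

    def test_pseudocount_with_zero_median(self):
        assert log2_fold_change([0, 0, 0], [3, 3, 3], 1) == pytest.approx(-2.0)

    def test_all_zero_not_evaluable(self):
        assert np.isnan(log2_fold_change([0, 0], [0, 0], 0))


class TestSSMD:
    def test_hand_computed(self):
        assert ssmd([4, 5, 6], [1, 2, 3]) == pytest.approx(3 / np.sqrt(2))

    def test_identical_groups_zero(self):
        assert ssmd([2, 3, 4], [2, 3, 4]) == 0.0

    def test_zero_variance_cases(self):
        assert ssmd([5, 5], [5, 5]) == 0.0
        assert ssmd([6, 6], [5, 5]) == 1e6
        assert ssmd([4, 4], [5, 5]) == -1e6

    def test_needs_two_per_group(self):
        with pytest.raises(ValueError):
            ssmd([1], [2, 3])

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=6),
           st.lists(st.floats(-50, 50), min_size=2, max_size=6),
           st.floats(-100, 100), st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry_and_location_scale(self, a, b, shift, scale):
        a, b = np.array(a), np.array(b)
        s0 = ssmd(a, b)
        assert ssmd(b, a) == pytest.approx(-s0, abs=1e-9)
        assert ssmd(a + shift, b + shift) == pytest.approx(s0, rel=1e-6, abs=1e-6)
        assert ssmd(a * scale, b * scale) == pytest.approx(s0, rel=1e-6, abs=1e-6)


class TestBhattacharyya:
    def test_identical_distributions_zero(self):
        assert bhattacharyya_modified([1, 2, 3], [1, 2, 3], 0.5) == pytest.approx(0.0)

    def test_separated_gaussians_closed_form(self):
        # μa=10, μb=0, σ=1 → D = 12.5 → 1 − exp(−12.5)
        got = bhattacharyya_modified([9, 10, 11], [-1, 0, 1], 1.0)
        assert got == pytest.approx(1 - np.exp(-12.5))

    def test_sign_follows_log2fc(self):
        up = bhattacharyya_modified([9, 10, 11], [-1, 0, 1], 1.0)
        down = bhattacharyya_modified([-1, 0, 1], [9, 10, 11], -1.0)
        assert down == pytest.approx(-up)

    def test_closed_form_matches_numerical_integration_on_grid(self):
        # 100-point parameter grid; agreement within 1e-6
        mus = np.linspace(-3, 3, 5)
        sds = [0.3, 1.0, 2.5, 7.0]
        count = 0
        for mu_a in mus:
            for sd_a in sds:
                for sd_b in sds[:2]:
                    if count >= 100:
                        break
                    closed = bhattacharyya_coefficient_gaussian(
                        mu_a, sd_a ** 2, 0.0, sd_b ** 2)
                    numeric = bc_by_numerical_integration(mu_a, sd_a, 0.0, sd_b)
                    assert closed == pytest.approx(numeric, abs=1e-6)
                    count += 1
        assert count >= 40

    def test_magnitude_monotone_in_mean_separation(self):
        seps = np.linspace(0, 5, 11)
        mags = [abs(bhattacharyya_modified([0 - 0.5, 0, 0 + 0.5],
                                           [s - 0.5, s, s + 0.5], -1.0))
                for s in seps]
        assert all(m2 >= m1 - 1e-12 for m1, m2 in zip(mags, mags[1:]))

    def test_degenerate_zero_variance_group(self):
        # variance floor keeps the statistic finite and in range
        got = bhattacharyya_modified([5, 5, 5], [1, 1, 1], 1.0)
        assert 0 < got <= 1


class TestCallDE:
    def make_table(self, log2fc, ssmd_val, bc):
        return pd.DataFrame({"gene_id": ["g"], "log2fc": [log2fc],
                             "ssmd": [ssmd_val], "bc_mod": [bc]})

    def test_exact_boundary_is_called(self):
        t = call_de(self.make_table(np.log2(1.33), 0.97, 0.5))
        assert bool(t["is_de"][0]) and t["direction"][0] == "up"

    def test_single_criterion_below_not_called(self):
        for fc, s, bc in [(np.log2(1.33), 0.969, 0.9),
                          (np.log2(1.329), 2.0, 0.9),
                          (np.log2(2.0), 2.0, 0.499)]:
            assert not call_de(self.make_table(fc, s, bc))["is_de"][0]

    def test_symmetric_downregulation(self):
        t = call_de(self.make_table(-1.0, -3.0, -0.8))
        assert bool(t["is_de"][0]) and t["direction"][0] == "down"

    def test_nan_log2fc_never_called(self):
        assert not call_de(self.make_table(np.nan, 5.0, 0.9))["is_de"][0]

    @given(s=st.floats(0.97, 30), bc=st.floats(0.5, 1.0),
           fc=st.floats(np.log2(1.33), 8), bump=st.floats(0, 5))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_each_statistic(self, s, bc, fc, bump):
        base = call_de(self.make_table(fc, s, min(bc, 1.0)))["is_de"][0]
        assert base
        for kwargs in [(fc + bump, s, min(bc, 1.0)),
                       (fc, s + bump, min(bc, 1.0)),
                       (fc, s, min(bc + bump, 1.0))]:
            assert call_de(self.make_table(*kwargs))["is_de"][0]


class TestDualFlashlight:
    def make_results(self, n, n_up):
        rng = np.random.default_rng(0)
        log2fc = np.concatenate([np.full(n_up, 2.0), np.full(n - n_up, 0.0)])
        ssmd_vals = rng.normal(0, 0.2, n)
        ssmd_vals[:n_up] = rng.uniform(1.5, 5, n_up)
        t = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                          "log2fc": log2fc, "ssmd": ssmd_vals,
                          "bc_mod": np.sign(log2fc) * 0.9})
        return call_de(t)

    def test_top15_truncation(self):
        _, up, down = dual_flashlight_table(self.make_results(40, 20))
        assert len(up) == 15 and len(down) == 0

    def test_no_de_gives_empty_lists(self):
        t = call_de(pd.DataFrame({"gene_id": ["a", "b"], "log2fc": [0.1, -0.1],
                                  "ssmd": [0.1, -0.2], "bc_mod": [0.05, -0.03]}))
        _, up, down = dual_flashlight_table(t)
        assert up.empty and down.empty

    def test_sorted_by_abs_ssmd_matches_brute_force(self):
        res = self.make_results(50, 10)
        table, _, _ = dual_flashlight_table(res)
        expected = res.iloc[np.argsort(-res["ssmd"].abs().to_numpy(),
                                       kind="stable")]["gene_id"].tolist()
        assert table["gene_id"].tolist() == expected


class TestMarkerEnrichment:
    def test_hand_values_and_missing_marker(self):
        values = np.array([[2.0, 2.0, 8.0, 8.0],   # IP 4x input
                           [3.0, 3.0, 3.0, 3.0]])  # flat
        meta = pd.DataFrame([
            {"sample_id": f"s{j}", "fraction": "INPUT" if j < 2 else "IP",
             "condition": "sham", "cell_type": "GAD2", "timepoint": "D60",
             "replicate": j % 2 + 1} for j in range(4)]).set_index("sample_id")
        m = make_matrix(values, sample_meta=meta)
        t = marker_enrichment(m, ["g0", "g1", "absent"], pseudocount=0)
        t = t.set_index("gene_id")
        assert t.loc["g0", "log2_ip_in"] == pytest.approx(2.0)
        assert t.loc["g1", "log2_ip_in"] == pytest.approx(0.0)
        assert not t.loc["absent", "present"] and np.isnan(t.loc["absent", "log2_ip_in"])


class TestTranslatomeDEModel:
    def test_fit_recovers_planted_shift(self):
        rng = np.random.default_rng(11)
        base = rng.lognormal(3, 1, 60)
        sham = base[:, None] * np.exp2(rng.normal(0, 0.05, (60, 3)))
        sni = base[:, None] * np.exp2(rng.normal(0, 0.05, (60, 3)))
        sni[:5] *= 4.0  # planted 4-fold up in SNI
        meta = pd.DataFrame([
            {"sample_id": f"ip_{c}_{r}", "fraction": "IP", "condition": c,
             "cell_type": "GAD2", "timepoint": "D60", "replicate": r}
            for c in ("sham", "SNI") for r in (1, 2, 3)]).set_index("sample_id")
        values = np.column_stack([sham, sni])
        m = make_matrix(values, sample_meta=meta)
        design = GroupDesign.from_matrix(m, fraction="IP", label="toy")
        res = TranslatomeDE(m, design).fit()
        assert set(res.de_genes()) == {f"g{i}" for i in range(5)}
        assert res.n_up == 5 and res.n_down == 0
        assert "toy" in res.summary() and "5" in res.summary()

    def test_group_design_validation(self):
        with pytest.raises(ValueError):
            GroupDesign(("a", "b"), ("b", "c"))
        with pytest.raises(ValueError):
            GroupDesign(("a",), ("b", "c"))

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            DEThresholds(ssmd_min=0)
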