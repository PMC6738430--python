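import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from telemeth.ewas import (
    Z_CAP, ProbeFilter, apply_probe_filter, bicor, bicor_matrix, r_to_pz,
    stratum_ewas,
)


def bicor_oracle(x, y):
    """Direct, loop-free-of-shortcuts transcription of the published biweight
    midcorrelation formula; independent of the library implementation."""
    def weighted(v):
        med = float(np.median(v))
        mad = float(np.median(np.abs(v - med)))
        if mad == 0:
            return v - np.mean(v)
        out = np.empty_like(v, dtype=float)
        for i, vi in enumerate(v):
            u = (vi - med) / (9.0 * mad)
            w = (1 - u**2) ** 2 if abs(u) < 1 else 0.0
            out[i] = (vi - med) * w
        return out

    a, b = weighted(np.asarray(x, float)), weighted(np.asarray(y, float))
    num = float(np.sum(a * b))
    den = float(np.sqrt(np.sum(a**2)) * np.sqrt(np.sum(b**2)))
    return num / den


finite_vec = hnp.arrays(
    np.float64, st.integers(8, 40),
    elements=st.floats(-50, 50, allow_nan=False),
)


class TestBicor:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=30)
        assert bicor(x, x) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("a", [2.5, -0.7])
    def test_affine_equivariance(self, rng, a):
        x = rng.normal(size=40)
        assert bicor(x, a * x + 3.0) == pytest.approx(np.sign(a), abs=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(30):
            x = rng.normal(size=50)
            y = 0.4 * x + rng.normal(size=50)
            assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_undefined_below_four_pairs(self):
        assert np.isnan(bicor([1, 2, 3], [1, 2, 4]))
        x = np.array([1.0, 2, 3, 4, np.nan, np.nan])
        y = np.array([np.nan, 2, 3, 4, 5, 6.0])
        assert np.isnan(bicor(x, y))  # only 3 complete pairs

    def test_undefined_for_constant_vector(self, rng):
        assert np.isnan(bicor(np.ones(10), rng.normal(size=10)))

    def test_mad_zero_falls_back_to_pearson(self, rng):
        # majority-constant vector: MAD = 0 but variance > 0
        x = np.array([0.0] * 12 + [1.0, 2.0, 3.0])
        y = rng.normal(size=15)
        # the oracle implements the same mean-centering fallback
        assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(finite_vec)
    def test_symmetry(self, x):
        rng = np.random.default_rng(0)
        y = rng.normal(size=x.size)
        a, b = bicor(x, y), bicor(y, x)
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, abs=1e-15)

    def test_monotone_affine_invariance(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert bicor(3 * x + 1, y) == pytest.approx(bicor(x, y), abs=1e-12)
        assert bicor(-2 * x, y) == pytest.approx(-bicor(x, y), abs=1e-12)

    def test_matrix_agrees_with_pairwise(self, rng):
        X = rng.normal(size=(6, 25))
        C = bicor_matrix(X)
        for i in range(6):
            for j in range(6):
                ref = 1.0 if i == j else bicor(X[i], X[j])
                assert C[i, j] == pytest.approx(ref, abs=1e-12)


class TestPZTransform:
    def test_zero_correlation_gives_null_stats(self):
        p, z = r_to_pz(np.array([0.0]), np.array([25]))
        assert p[0] == 1.0 and z[0] == 0.0

    def test_perfect_correlation_capped(self):
        p, z = r_to_pz(np.array([1.0, -1.0]), np.array([10, 10]))
        assert (p == 0).all()
        assert z[0] == Z_CAP and z[1] == -Z_CAP

    def test_p_monotone_decreasing_in_abs_r(self):
        rs = np.linspace(0.05, 0.95, 15)
        p, _ = r_to_pz(rs, np.full(15, 40))
        assert (np.diff(p) < 0).all()

    def test_sign_consistency(self, rng):
        r = rng.uniform(-0.9, 0.9, size=50)
        _, z = r_to_pz(r, np.full(50, 30))
        nz = r != 0
        assert (np.sign(z[nz]) == np.sign(r[nz])).all()


@pytest.fixture()
def toy_annotation():
    return pd.DataFrame(
        {
            "cpg_id": [f"cg{i}" for i in range(20)],
            "chrom": ["chr1"] * 8 + ["chrX"] * 4 + ["chr2"] * 8,
            "pos": np.arange(20) * 1000,
            "gene": ["G"] * 20,
            "island_relation": ["OpenSea"] * 20,
        }
    )


class TestProbeFilter:
    def test_empty_filter_is_identity(self, toy_annotation):
        kept = apply_probe_filter(toy_annotation, ProbeFilter())
        assert list(kept) == list(toy_annotation["cpg_id"])

    def test_autosomes_only_drops_chrx(self, toy_annotation):
        kept = apply_probe_filter(toy_annotation, ProbeFilter(autosomes_only=True))
        assert len(kept) == 16 and not any(k.startswith("cg1") and int(k[2:]) in
                                           range(8, 12) for k in kept)

    def test_overlapping_exclusions_remove_union(self, toy_annotation):
        """Removal equals the set union of the exclusion lists (set-algebra
        oracle on the toy annotation)."""
        ex1 = frozenset({"cg0", "cg1", "cg2"})
        ex2 = frozenset({"cg2", "cg3", "cg15"})
        kept = apply_probe_filter(
            toy_annotation,
            ProbeFilter(exclude_snp_probes=ex1, exclude_multimap_probes=ex2),
        )
        expected = set(toy_annotation["cpg_id"]) - (set(ex1) | set(ex2))
        assert set(kept) == expected

    def test_unknown_exclusion_ids_ignored(self, toy_annotation):
        kept = apply_probe_filter(
            toy_annotation, ProbeFilter(exclude_snp_probes=frozenset({"cgNOPE"}))
        )
        assert len(kept) == 20


class TestStratumEwas:
    def _trait(self, beta, y):
        return pd.DataFrame(
            {"sample_id": beta.columns, "residual_ltl": y, "stratum_id": "s1"}
        )

    def test_planted_cpg_attains_smallest_p(self, rng):
        n = 400
        X = rng.normal(0.5, 0.05, size=(200, n)).clip(0, 1)
        y = 8.0 * X[37] + rng.normal(size=n) * 0.1
        beta = pd.DataFrame(X, index=[f"cg{i}" for i in range(200)],
                            columns=[f"s{i}" for i in range(n)])
        res = stratum_ewas(beta, self._trait(beta, y))
        assert res.loc[res["p"].idxmin(), "cpg"] == "cg37"

    def test_pairwise_complete_counts(self, rng):
        X = rng.normal(size=(5, 30))
        X[2, :10] = np.nan
        beta = pd.DataFrame(X, index=[f"cg{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(30)])
        res = stratum_ewas(beta, self._trait(beta, rng.normal(size=30)))
        assert res.set_index("cpg").loc["cg2", "n"] == 20
        assert res.set_index("cpg").loc["cg0", "n"] == 30

    def test_all_probes_filtered_is_error(self, rng, toy_annotation):
        beta = pd.DataFrame(
            rng.normal(size=(4, 10)),
            index=["cg8", "cg9", "cg10", "cg11"],  # all chrX in the toy annotation
            columns=[f"s{i}" for i in range(10)],
        )
        with pytest.raises(ValueError, match="filtered out|all probes"):
            stratum_ewas(
                beta, self._trait(beta, rng.normal(size=10)),
                ProbeFilter(autosomes_only=True), toy_annotation,
            )

    def test_missing_trait_sample_rejected(self, rng):
        beta = pd.DataFrame(rng.normal(size=(3, 8)),
                            index=list("abc"), columns=[f"s{i}" for i in range(8)])
        trait = pd.DataFrame(
            {"sample_id": ["s0", "nope"], "residual_ltl": [0.1, 0.2],
             "stratum_id": "s1"}
        )
        with pytest.raises(ValueError, match="absent"):
            stratum_ewas(beta, trait)
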