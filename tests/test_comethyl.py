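import numpy as np
import pandas as pd
import pytest

from telemeth import synthdata as sd
from telemeth.comethyl import (
    GREY, NetworkConfig, _tom_from_adjacency, cohort_eigengenes,
    consensus_tom, detect_modules, module_eigengene, module_trait_meta,
)
from telemeth.ewas import Z_CAP


@pytest.fixture(scope="module")
def block_dataset():
    """Three cohorts with two planted latent-factor blocks and one
    cell-type-driven block."""
    specs = [
        sd.StratumSpec(c, "female", "European", "b1", 60, (30, 80),
                       7.0, 0.7, -0.3, 0.0)
        for c in ("FHS", "JHS", "WHI")
    ]
    return sd.generate_cohorts(
        specs, n_probes=400, n_causal=0, seed=5,
        module_blocks=[(80, 0.7, "latent"), (80, 0.7, "latent"),
                       (60, 0.7, "celltype:0")],
    )


def _by_cohort(beta, pheno):
    return {
        c: beta[pheno.loc[pheno["cohort"] == c, "sample_id"]]
        for c in pheno["cohort"].unique()
    }


class TestTom:
    def test_saturated_adjacency_gives_unit_tom(self):
        A = np.ones((3, 3))
        tom = _tom_from_adjacency(A)
        np.testing.assert_allclose(tom, 1.0, atol=1e-12)

    def test_range_symmetry_and_diagonal(self, rng):
        C = np.clip(rng.uniform(-1, 1, size=(30, 30)), -1, 1)
        A = np.abs((C + C.T) / 2) ** 6
        np.fill_diagonal(A, 1.0)
        tom = _tom_from_adjacency(A)
        assert ((tom >= 0) & (tom <= 1)).all()
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_identical_cohorts_consensus_idempotent(self, block_dataset):
        beta, pheno, _, _ = block_dataset
        one = beta[pheno.loc[pheno["cohort"] == "FHS", "sample_id"]]
        cfg = NetworkConfig(n_subsample=150, seed=0)
        t1, probes = consensus_tom([one], cfg)
        t3, _ = consensus_tom([one, one.copy(), one.copy()], cfg)
        np.testing.assert_allclose(t1, t3, atol=1e-10)

    def test_minimum_consensus_bounded_by_each_cohort(self, block_dataset):
        beta, pheno, _, _ = block_dataset
        byc = _by_cohort(beta, pheno)
        cfg = NetworkConfig(n_subsample=120, consensus_quantile=0.0, seed=1)
        cons, probes, toms = consensus_tom(
            list(byc.values()), cfg, return_cohort_toms=True
        )
        off = ~np.eye(len(probes), dtype=bool)
        for t in toms:
            assert (cons[off] <= t[off] + 1e-12).all()

    def test_too_few_samples_rejected(self, block_dataset):
        beta, pheno, _, _ = block_dataset
        tiny = beta.iloc[:, :10]
        with pytest.raises(ValueError, match="20 samples"):
            consensus_tom([tiny], NetworkConfig(n_subsample=50))


class TestModuleDetection:
    def test_two_planted_blocks_recovered(self, block_dataset):
        """Block-model simulation: both latent-factor modules recovered with
        adjusted Rand >= 0.9 against the planted membership."""
        from sklearn.metrics import adjusted_rand_score

        beta, pheno, _, truth = block_dataset
        byc = _by_cohort(beta, pheno)
        cfg = NetworkConfig(n_subsample=400, min_module_size=30, seed=0)
        tom, probes = consensus_tom(list(byc.values()), cfg)
        allb = pd.concat(byc.values(), axis=1)
        assign = detect_modules(tom, cfg, beta=allb, probe_ids=probes)
        # score recovery on the latent-factor blocks; the cell-type-driven
        # block legitimately recruits cell-discriminating background probes
        latent = [m for m, d in truth.planted_module_blocks if d == "latent"]
        mask = probes.isin(latent[0] | latent[1])
        true = np.where(probes[mask].isin(latent[0]), 0, 1)
        pred = pd.factorize(assign[np.asarray(mask)])[0]
        assert adjusted_rand_score(true, pred) >= 0.9
        assert len(set(assign) - {GREY}) >= 3

    def test_tiny_merge_threshold_never_merges(self, block_dataset):
        beta, pheno, _, _ = block_dataset
        byc = _by_cohort(beta, pheno)
        cfg = NetworkConfig(n_subsample=300, min_module_size=25, seed=0,
                            merge_threshold=1e-6)
        tom, probes = consensus_tom(list(byc.values()), cfg)
        allb = pd.concat(byc.values(), axis=1)
        merged = detect_modules(tom, cfg, beta=allb, probe_ids=probes)
        unmerged = detect_modules(tom, cfg, probe_ids=probes)
        # same non-grey partition up to label names
        assert (
            pd.factorize(merged)[0] == pd.factorize(unmerged)[0]
        ).all()

    def test_min_module_size_gate_yields_grey(self, rng):
        X = rng.normal(size=(40, 50))
        from telemeth.ewas import bicor_matrix

        A = np.abs(bicor_matrix(X)) ** 6
        tom = _tom_from_adjacency(A)
        cfg = NetworkConfig(n_subsample=40, min_module_size=100, seed=0)
        assign = detect_modules(tom, cfg)
        assert (assign == GREY).all()

    def test_null_data_mostly_grey(self, rng):
        X = rng.normal(size=(200, 80))
        from telemeth.ewas import bicor_matrix

        A = np.abs(bicor_matrix(X)) ** 6
        tom = _tom_from_adjacency(A)
        assign = detect_modules(tom, NetworkConfig(n_subsample=200, seed=0))
        assert (assign == GREY).mean() >= 0.9

    def test_probe_permutation_permutes_labels(self, block_dataset):
        beta, pheno, _, _ = block_dataset
        byc = _by_cohort(beta, pheno)
        cfg = NetworkConfig(n_subsample=10**6, min_module_size=30, seed=0)
        rng = np.random.default_rng(3)
        perm = rng.permutation(beta.shape[0])
        byc_p = {c: b.iloc[perm] for c, b in byc.items()}
        tom, probes = consensus_tom(list(byc.values()), cfg)
        tom_p, probes_p = consensus_tom(list(byc_p.values()), cfg)
        a = detect_modules(tom, cfg, probe_ids=probes)
        b = detect_modules(tom_p, cfg, probe_ids=probes_p)
        merged = pd.concat([a.rename("a"), b.rename("b")], axis=1)
        tab = merged.groupby(["a", "b"]).size().unstack(fill_value=0)
        # one-to-one correspondence between label sets
        assert ((tab > 0).sum(axis=1) == 1).all()


class TestEigengene:
    def test_rank_one_module_recovers_direction(self, rng):
        v = rng.normal(size=30)
        M = pd.DataFrame(np.tile(v[:, None], (1, 5)))
        e = module_eigengene(M)
        assert abs(np.corrcoef(e, v)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_pc1_variance_optimality(self, rng):
        X = rng.normal(size=(40, 8))
        X[:, :4] += rng.normal(size=(40, 1))  # shared factor
        M = pd.DataFrame(X)
        e = module_eigengene(M).to_numpy()
        Xs = (X - X.mean(0)) / X.std(0)
        var_e = np.mean((Xs.T @ e) ** 2)
        for j in range(8):
            var_j = np.mean((Xs.T @ (Xs[:, j] / np.linalg.norm(Xs[:, j]))) ** 2)
            assert var_e >= var_j - 1e-10

    def test_sign_alignment_invariant_to_global_flip(self, rng):
        for _ in range(5):
            X = rng.normal(0.5, 0.1, size=(25, 6))
            e1 = module_eigengene(pd.DataFrame(X))
            e2 = module_eigengene(pd.DataFrame(-X + 1.0))
            # alignment ties the eigengene to mean methylation, so a global
            # reflection of the data flips the eigengene consistently
            assert abs(np.corrcoef(e1, e2)[0, 1]) == pytest.approx(1, abs=1e-8)

    def test_constant_module_rejected(self):
        M = pd.DataFrame(np.ones((10, 3)))
        with pytest.raises(ValueError, match="constant"):
            module_eigengene(M)

    def test_minimum_shape_enforced(self, rng):
        with pytest.raises(ValueError):
            module_eigengene(pd.DataFrame(rng.normal(size=(2, 5))))


class TestModuleTraitMeta:
    def _setup(self, block_dataset):
        beta, pheno, _, truth = block_dataset
        byc = _by_cohort(beta, pheno)
        cfg = NetworkConfig(n_subsample=400, min_module_size=30, seed=0)
        tom, probes = consensus_tom(list(byc.values()), cfg)
        allb = pd.concat(byc.values(), axis=1)
        assign = detect_modules(tom, cfg, beta=allb, probe_ids=probes)
        return beta, pheno, truth, assign

    def test_trait_equal_to_eigengene_hits_cap(self, block_dataset):
        beta, pheno, truth, assign = self._setup(block_dataset)
        sid = pheno["stratum_id"].iloc[0]
        samples = pheno.loc[pheno["stratum_id"] == sid, "sample_id"]
        m = sorted(set(assign) - {GREY})[0]
        cpgs = assign.index[assign == m]
        eg = module_eigengene(beta.loc[cpgs, samples].T)
        traits = {sid: pd.DataFrame({"self": eg}, index=samples)}
        betas = {sid: beta[samples]}
        out = module_trait_meta(assign, betas, traits)
        assert out.loc[m, ("self", "z")] == pytest.approx(Z_CAP)

    def test_null_trait_stays_small(self, block_dataset):
        beta, pheno, truth, assign = self._setup(block_dataset)
        rng = np.random.default_rng(17)
        betas, traits = {}, {}
        for sid, sub in pheno.groupby("stratum_id"):
            samples = sub["sample_id"]
            betas[sid] = beta[samples]
            traits[sid] = pd.DataFrame(
                {"noise": rng.normal(size=len(samples))},
                index=samples,
            )
        out = module_trait_meta(assign, betas, traits)
        assert (out.xs("z", axis=1, level=1).abs() < 3.5).all().all()

    def test_celltype_driven_module_tracks_its_proportion(self, block_dataset):
        """The planted cell-type-driven block shows the strongest meta-Z
        against that cell proportion (the blood-cell-confounding pattern)."""
        beta, pheno, truth, assign = self._setup(block_dataset)
        cell_block = next(
            members for members, d in truth.planted_module_blocks
            if d == "celltype:0"
        )
        props = truth.cell_proportions
        betas, traits = {}, {}
        for sid, sub in pheno.groupby("stratum_id"):
            samples = sub["sample_id"]
            betas[sid] = beta[samples]
            traits[sid] = pd.DataFrame(
                {"celltype_0": props.loc[samples, "celltype_0"]},
                index=samples,
            )
        out = module_trait_meta(assign, betas, traits)
        zcol = out[("celltype_0", "z")].abs()
        # find the detected module that best overlaps the planted block
        overlap = {
            m: np.mean([c in cell_block for c in assign.index[assign == m]])
            for m in zcol.index
        }
        planted_module = max(overlap, key=overlap.get)
        assert overlap[planted_module] > 0.5
        assert zcol.idxmax() == planted_module
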