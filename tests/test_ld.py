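"""Two-locus LD: EM haplotype frequencies, D/D'/r2/LOD, HWE, surrogates."""

import numpy as np
import pytest

from inv17q import ld
from inv17q.ld import TwoLocusCounts
from inv17q.simulate import simulate_ld_pair
from tests.test_genotype_io import make_gm


def _batch_loglik(freqs: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood of many candidate frequency vectors (m, 4)
    against a 3x3 genotype table — written independently of the EM code."""
    dosage = [(0, 0), (0, 1), (1, 0), (1, 1)]
    probs = np.zeros((freqs.shape[0], 3, 3))
    for h1 in range(4):
        for h2 in range(4):
            i = dosage[h1][0] + dosage[h2][0]
            j = dosage[h1][1] + dosage[h2][1]
            probs[:, i, j] += freqs[:, h1] * freqs[:, h2]
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(probs > 0, np.log(np.maximum(probs, 1e-300)), -np.inf)
        terms = np.where(table[None] > 0, table[None] * lp, 0.0)
    return terms.sum(axis=(1, 2))


def _simplex_grid(lo: np.ndarray, hi: np.ndarray, step: float) -> np.ndarray:
    """(p_AB, p_Ab, p_aB) lattice within [lo, hi], p_ab the remainder."""
    axes = [np.arange(lo[k], hi[k] + step / 2, step) for k in range(3)]
    g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    rest = 1.0 - g.sum(axis=1)
    ok = rest >= -1e-12
    return np.column_stack([g[ok], np.maximum(rest[ok], 0.0)])


def grid_search_em_oracle(table: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Brute-force maximum-likelihood haplotype frequencies on a lattice.

    A coarse pass over the full simplex is refined on a ``step`` lattice
    around the coarse argmax; fully independent of the EM implementation.
    """
    coarse = _simplex_grid(np.zeros(3), np.ones(3), 0.01)
    best = coarse[np.argmax(_batch_loglik(coarse, table))]
    lo = np.maximum(best[:3] - 0.015, 0.0)
    hi = np.minimum(best[:3] + 0.015, 1.0)
    fine = _simplex_grid(lo, hi, step)
    return fine[np.argmax(_batch_loglik(fine, table))]


class TestEmHaplotypes:
    def test_perfect_coupling(self):
        # only AABB and aabb double homozygotes
        t = np.zeros((3, 3))
        t[0, 0] = 30
        t[2, 2] = 20
        res = ld.pair_ld(TwoLocusCounts(t))
        assert res.p_AB == pytest.approx(0.6)
        assert res.p_ab == pytest.approx(0.4)
        assert res.D_prime == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_independence_gives_zero_d(self):
        # counts exactly at HWE x independence for p_a = p_b = 0.5
        t = np.array([[4.0, 8, 4], [8, 16, 8], [4, 8, 4]])
        res = ld.pair_ld(TwoLocusCounts(t))
        assert res.D == pytest.approx(0.0, abs=1e-9)
        assert res.lod == pytest.approx(0.0, abs=1e-9)
        assert res.r2 == pytest.approx(0.0, abs=1e-9)

    def test_em_matches_grid_search_oracle(self, rng):
        for _ in range(10):
            t = rng.integers(0, 8, size=(3, 3)).astype(float)
            if t.sum() == 0 or t.sum() > 50:
                continue
            counts = TwoLocusCounts(t)
            em = ld.em_haplotypes(counts)
            oracle = grid_search_em_oracle(t)
            assert np.max(np.abs(em.freqs - oracle)) < 2e-3

    def test_symmetric_coupling_stats(self):
        t = np.zeros((3, 3))
        t[0, 0] = 50
        t[2, 2] = 50
        res = ld.pair_ld(TwoLocusCounts(t))
        assert res.D == pytest.approx(0.25)
        assert res.D_prime == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_r2_identity_holds(self, rng):
        for _ in range(5):
            t = rng.integers(1, 10, size=(3, 3)).astype(float)
            res = ld.pair_ld(TwoLocusCounts(t))
            p_A = res.p_AB + res.p_Ab
            p_B = res.p_AB + res.p_aB
            expected = res.D**2 / (p_A * (1 - p_A) * p_B * (1 - p_B))
            assert res.r2 == pytest.approx(expected, abs=1e-12)

    def test_allele_swap_negates_d(self, rng):
        t = rng.integers(1, 10, size=(3, 3)).astype(float)
        res1 = ld.pair_ld(TwoLocusCounts(t))
        res2 = ld.pair_ld(TwoLocusCounts(t[::-1, :]))  # swap labels at locus 1
        assert res2.D == pytest.approx(-res1.D, abs=1e-6)
        assert abs(res2.D_prime) == pytest.approx(abs(res1.D_prime), abs=1e-6)
        assert res2.r2 == pytest.approx(res1.r2, abs=1e-6)
        assert res2.lod == pytest.approx(res1.lod, abs=1e-6)

    def test_loglik_nondecreasing_path(self):
        # EM raises internally if the likelihood ever decreases; a tricky
        # double-het-heavy table exercises many iterations
        t = np.array([[2.0, 5, 1], [4, 30, 6], [1, 7, 3]])
        res = ld.em_haplotypes(TwoLocusCounts(t))
        assert res.converged

    def test_monomorphic_locus_error(self):
        t = np.zeros((3, 3))
        t[0, 0] = 10
        t[0, 2] = 10
        with pytest.raises(ld.MonomorphicLocusError, match="locus1"):
            ld.pair_ld(TwoLocusCounts(t))

    def test_recovery_from_known_frequencies(self):
        counts = simulate_ld_pair(10_000, 0.55, 0.15, 0.15, 0.15, seed=2)
        res = ld.pair_ld(counts)
        truth = np.array([0.55, 0.15, 0.15, 0.15])
        assert np.max(np.abs(res.freqs - truth)) < 0.02
        p_A, p_B = 0.7, 0.7
        D = 0.55 - p_A * p_B
        r2_true = D**2 / (p_A * 0.3 * p_B * 0.3)
        assert res.r2 == pytest.approx(r2_true, abs=0.05)


class TestHwe:
    @pytest.mark.parametrize(
        "counts,chi2,pmax",
        [((25, 50, 25), 0.0, None), ((81, 18, 1), 0.0, None)],
    )
    def test_exact_hwe(self, counts, chi2, pmax):
        c, p = ld.hwe_chi2(*counts)
        assert c == pytest.approx(chi2, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_extreme_departure(self):
        c, p = ld.hwe_chi2(50, 0, 50)
        assert c == pytest.approx(100.0)
        assert p < 1e-20

    def test_monomorphic_convention(self):
        assert ld.hwe_chi2(100, 0, 0) == (0.0, 1.0)


class TestSelectSurrogates:
    def _panel(self, rng, n=400):
        """Target SNP + candidates at controlled distances/LD."""
        q = 0.3
        dos_t = rng.binomial(2, q, n)
        genos = np.array(["AA", "AC", "CC"])

        def linked(dosage, flip_rate):
            out = dosage.copy()
            flip = rng.random(n) < flip_rate
            out[flip] = rng.binomial(2, q, int(flip.sum()))
            return out

        cols = {
            "target": genos[dos_t],
            "near_strong": genos[linked(dos_t, 0.05)],
            "far_strong": genos[linked(dos_t, 0.02)],
            "weak": genos[linked(dos_t, 0.95)],
            "outside": genos[linked(dos_t, 0.0)],
            "hwe_bad": np.array(["AA" if d != 1 else "AC" for d in np.zeros(n, int)]),
        }
        positions = {
            "target": 1_000_000,
            "near_strong": 1_000_500,
            "far_strong": 965_000,
            "weak": 1_030_000,
            "outside": 1_050_001,
            "hwe_bad": 1_010_000,
        }
        gm = make_gm(
            [list(v) for v in cols.values()],
            positions=[positions[k] for k in cols],
        )
        for j, name in enumerate(cols):
            gm.snps[j] = type(gm.snps[j])(
                snp_id=name, chrom="17", pos=positions[name],
                allele_a=gm.snps[j].allele_a, allele_b=gm.snps[j].allele_b,
            )
        return gm

    def test_ranking_window_and_hwe(self, rng):
        gm = self._panel(rng)
        choice = ld.select_surrogates(gm, "target")
        # window is closed at 50 kb: 50 001 bp candidate excluded entirely
        assert "outside" not in set(choice.candidates["snp_id"])
        # HWE-violating candidate never chosen
        assert "hwe_bad" not in choice.chosen
        assert choice.chosen == ["far_strong", "near_strong"]
        lods = choice.candidates.set_index("snp_id")["lod"]
        assert lods["far_strong"] > lods["near_strong"] > lods["weak"]

    def test_window_boundary_inclusive(self, rng):
        gm = self._panel(rng)
        gm.snps[4] = type(gm.snps[4])(
            snp_id="outside", chrom="17", pos=1_050_000,
            allele_a=gm.snps[4].allele_a, allele_b=gm.snps[4].allele_b,
        )
        choice = ld.select_surrogates(gm, "target")
        assert "outside" in set(choice.candidates["snp_id"])

    def test_lod_tie_broken_by_distance(self, rng):
        # exact-HWE composition at q = 0.4, n = 300: (108, 144, 48)
        dos = np.array([0] * 108 + [1] * 144 + [2] * 48)
        rng.shuffle(dos)
        genos = np.array(["AA", "AC", "CC"])
        col = genos[dos]
        gm = make_gm(
            [list(col), list(col), list(col)], positions=[1000, 6000, 1500]
        )
        choice = ld.select_surrogates(gm, "snp0", window=50_000)
        # identical columns -> identical LOD; nearer candidate ranks first
        assert choice.chosen == ["snp2", "snp1"]

    def test_no_qualifying_candidate(self, rng):
        n = 200
        genos = np.array(["AA", "AC", "CC"])
        gm = make_gm(
            [list(genos[rng.binomial(2, 0.3, n)]) for _ in range(2)],
            positions=[1000, 2000],
        )
        choice = ld.select_surrogates(gm, "snp0", lod_min=1e6)
        assert choice.chosen == []
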