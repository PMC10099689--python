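"""EHH/iHS/XPEHH against brute-force pair-counting and hand-worked values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsnscan.haplotype_stats import (
    _ehh_scan,

    _r2_from_haplotypes,
    ehh,
    ihs,
    ld_decay_curve,
    pairwise_r2,
    xpehh,
)
from tsnscan.io_formats import HaplotypeMatrix, PopulationPanel
from tsnscan.synthetic_data import (
    EHH_FIXTURE_CORE,
    ehh_fixture_matrix,
)

# hand-worked integrals of the 8-haplotype fixture (trapezoids over the
# four truncated EHH curves around the core at position 5000)
FIXTURE_IHH_D = 3250.0
FIXTURE_IHH_A = 3041.0 + 2.0 / 3.0


def _matrix(calls, positions=None, ancestral=None):
    calls = np.asarray(calls, dtype=np.int8)
    m, n = calls.shape
    return HaplotypeMatrix(
        chrom="chr1",
        positions=(
            np.arange(1, m + 1) * 1000 if positions is None else np.asarray(positions)
        ),
        ref_allele=np.array(["A"] * m, dtype=object),
        alt_allele=np.array(["G"] * m, dtype=object),
        ancestral=(
            np.zeros(m, dtype=np.int8) if ancestral is None else np.asarray(ancestral, dtype=np.int8)
        ),
        calls=calls,
        sample_ids=[f"s{k}" for k in range(n // 2)],
    )


def _brute_ehh(calls, positions, core, cols, direction, threshold):
    """Explicit haplotype-string grouping, recomputed from scratch at every
    flanking marker."""
    K = len(cols)
    total = K * (K - 1) / 2
    step = -1 if direction == "upstream" else 1
    offsets, values = [0], [1.0]
    decayed = False
    j = core + step
    while 0 <= j < calls.shape[0]:
        span = range(core + step, j + step, step)
        groups = {}
        for rank, h in enumerate(cols):
            word = []
            broken = False
            for m in span:
                v = int(calls[m, h])
                if v < 0:
                    broken = True
                    break
                word.append(v)
            key = ("broken", rank) if broken else tuple(word)
            groups.setdefault(key, 0)
            groups[key] += 1
        e = sum(k * (k - 1) / 2 for k in groups.values()) / total
        offsets.append(int(positions[j] - positions[core]))
        values.append(e)
        if e < threshold:
            decayed = True
            break
        j += step
    return np.array(offsets), np.array(values), decayed


class TestEhh:
    def test_identical_carriers_never_decay(self):
        hm = _matrix(np.zeros((6, 8)))
        up, down = ehh(hm, core=3, allele_class="all")
        assert (up.ehh == 1).all() and (down.ehh == 1).all()
        assert not up.decayed and not down.decayed

    def test_two_equal_groups_at_first_flank(self):
        hm = ehh_fixture_matrix()
        _, down = ehh(hm, EHH_FIXTURE_CORE, "derived")
        # K=4 derived carriers split 2+2: (C(2,2)+C(2,2))/C(4,2) = 2/6
        np.testing.assert_allclose(down.ehh[1], 2 / 6)

    def test_small_carrier_class_is_missing(self):
        hm = _matrix([[0] * 8, [1] + [0] * 7, [0] * 8])
        assert ehh(hm, core=1, allele_class="derived") is None

    def test_curves_start_at_one_and_never_increase(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n, m = rng.integers(4, 24), rng.integers(4, 16)
            n += n % 2
            hm = _matrix(rng.integers(0, 2, (m, n)))
            core = int(rng.integers(0, m))
            pair = ehh(hm, core, "all")
            for curve in pair:
                assert curve.ehh[0] == 1.0
                assert (np.diff(curve.ehh) <= 1e-12).all()

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_grouping(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        m = int(rng.integers(3, 21))
        calls = rng.integers(0, 2, (m, n)).astype(np.int8)
        calls[rng.random((m, n)) < 0.07] = -1
        positions = np.sort(rng.choice(10**6, m, replace=False)) + 1
        core = int(rng.integers(0, m))
        cols = np.arange(n)
        for direction in ("upstream", "downstream"):
            got = _ehh_scan(calls, positions, core, cols, direction, 0.05)
            want = _brute_ehh(calls, positions, core, cols, direction, 0.05)
            np.testing.assert_array_equal(got[0], want[0])
            np.testing.assert_allclose(got[1], want[1], atol=1e-12)
            assert got[2] == want[2]


class TestIhs:
    def test_fixture_hand_trapezoids(self):
        hm = ehh_fixture_matrix()
        panel = PopulationPanel({f"S{k + 1}": "P" for k in range(4)})
        result = ihs(hm, panel, "P", min_maf=0.05, bins=50)
        row = result.iloc[EHH_FIXTURE_CORE]
        np.testing.assert_allclose(row.ihh_d, FIXTURE_IHH_D, atol=1e-9)
        np.testing.assert_allclose(row.ihh_a, FIXTURE_IHH_A, atol=1e-9)
        np.testing.assert_allclose(
            row.ihs, np.log(FIXTURE_IHH_A / FIXTURE_IHH_D), atol=1e-12
        )

    def test_mirror_decay_gives_zero(self):
        # ancestral and derived carriers see identical flanking patterns,
        # decaying to singletons before both edges
        flank = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        split = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        calls = np.stack(
            [flank, split, np.array([1, 1, 1, 1, 0, 0, 0, 0]), split, flank]
        )
        hm = _matrix(calls)
        panel = PopulationPanel({f"s{k}": "P" for k in range(4)})
        result = ihs(hm, panel, "P")
        assert result.iloc[2].ihs == 0.0

    def test_edge_failure_is_missing(self):
        # derived carriers identical to the chromosome end: no decay
        calls = np.zeros((5, 8), dtype=np.int8)
        calls[2, :4] = 1
        hm = _matrix(calls)
        panel = PopulationPanel({f"s{k}": "P" for k in range(4)})
        assert np.isnan(ihs(hm, panel, "P").iloc[2].ihs)

    def test_invariance_under_sample_permutation_and_hap_swap(self):
        hm = ehh_fixture_matrix()
        panel = PopulationPanel({f"S{k + 1}": "P" for k in range(4)})
        base = ihs(hm, panel, "P")

        perm = [2, 0, 3, 1]
        cols = np.ravel([[2 * p, 2 * p + 1] for p in perm])
        hm_perm = HaplotypeMatrix(
            chrom=hm.chrom,
            positions=hm.positions,
            ref_allele=hm.ref_allele,
            alt_allele=hm.alt_allele,
            ancestral=hm.ancestral,
            calls=hm.calls[:, cols],
            sample_ids=[hm.sample_ids[p] for p in perm],
        )
        np.testing.assert_allclose(
            ihs(hm_perm, panel, "P")["ihs"], base["ihs"], equal_nan=True
        )

        swap = np.ravel([[2 * k + 1, 2 * k] for k in range(4)])
        hm_swap = HaplotypeMatrix(
            chrom=hm.chrom,
            positions=hm.positions,
            ref_allele=hm.ref_allele,
            alt_allele=hm.alt_allele,
            ancestral=hm.ancestral,
            calls=hm.calls[:, swap],
            sample_ids=hm.sample_ids,
        )
        np.testing.assert_allclose(
            ihs(hm_swap, panel, "P")["ihs"], base["ihs"], equal_nan=True
        )


class TestXpehh:
    def test_identical_populations_score_zero(self):
        flank = np.array([0, 1, 0, 1])
        split = np.array([0, 0, 1, 1])
        block = np.stack([flank, split, np.ones(4, dtype=int), split, flank])
        calls = np.concatenate([block, block], axis=1)  # pop B = copy of A
        hm = _matrix(calls)
        panel = PopulationPanel(
            {f"s{k}": ("A" if k < 2 else "B") for k in range(4)}
        )
        result = xpehh(hm, panel, "A", "B")
        defined = result["xpehh"].dropna()
        assert len(defined) > 0
        np.testing.assert_allclose(defined, 0.0, atol=1e-12)

    def test_longer_haplotypes_in_pop_a_score_positive(self):
        # pop A: two 6-haplotype families that shatter to singletons only at
        # the outermost markers; pop B: 12 distinct haplotypes that shatter
        # right away.  A's EHH dominates B's at every offset, so the
        # log-ratio at the central core must be positive.
        m = 13
        core = 6
        a = np.zeros((m, 12), dtype=np.int8)
        b = np.zeros((m, 12), dtype=np.int8)
        for k in range(12):
            member = k % 6
            family = k // 6
            for marker in (5, 4, 3, 7, 8, 9):  # A: long family haplotypes
                a[marker, k] = family
            for j, marker in enumerate((2, 1, 0)):  # then shatter by member
                a[marker, k] = (member >> j) & 1
            for j, marker in enumerate((10, 11, 12)):
                a[marker, k] = (member >> j) & 1
            for j, marker in enumerate((5, 4, 3, 2)):  # B: shatter immediately
                b[marker, k] = (k >> j) & 1
            for j, marker in enumerate((7, 8, 9, 10)):
                b[marker, k] = (k >> j) & 1
            a[core, k] = family
            b[core, k] = k & 1
        calls = np.concatenate([a, b], axis=1)
        hm = _matrix(calls)
        panel = PopulationPanel(
            {f"s{k}": ("A" if k < 6 else "B") for k in range(12)}
        )
        result = xpehh(hm, panel, "A", "B")
        assert result["xpehh"].notna().any()
        assert result["xpehh"][core] > 0

    def test_needs_four_haplotypes_each(self):
        hm = _matrix(np.zeros((3, 6)))
        panel = PopulationPanel({"s0": "A", "s1": "B", "s2": "B"})
        with pytest.raises(ValueError, match="4 haplotypes"):
            xpehh(hm, panel, "A", "B")


def _r2_oracle(x, y):
    """2×2 haplotype contingency table, coded independently."""
    n = len(x)
    tab = np.zeros((2, 2))
    for a, b in zip(x, y):
        tab[a, b] += 1
    tab /= n
    pa = tab[1].sum()
    pb = tab[:, 1].sum()
    d = tab[1, 1] - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


class TestPairwiseR2:
    def test_perfect_ld(self):
        x = np.array([1] * 5 + [0] * 5, dtype=np.int8)
        hm = _matrix(np.stack([x, x]))
        panel = PopulationPanel({f"s{k}": "P" for k in range(5)})
        assert pairwise_r2(hm, panel, "P", 0, 1).r2 == pytest.approx(1.0)

    def test_independence(self):
        x = np.array([1, 1, 0, 0] * 2, dtype=np.int8)
        y = np.array([1, 0, 1, 0] * 2, dtype=np.int8)
        hm = _matrix(np.stack([x, y]))
        panel = PopulationPanel({f"s{k}": "P" for k in range(4)})
        assert pairwise_r2(hm, panel, "P", 0, 1).r2 == pytest.approx(0.0)

    def test_matches_contingency_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            x = rng.integers(0, 2, 30)
            y = rng.integers(0, 2, 30)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            np.testing.assert_allclose(
                _r2_from_haplotypes(x.astype(np.int8), y.astype(np.int8)),
                _r2_oracle(x, y),
                atol=1e-12,
            )

    def test_monomorphic_is_missing(self):
        x = np.zeros(8, dtype=np.int8)
        y = np.array([1, 0] * 4, dtype=np.int8)
        assert np.isnan(_r2_from_haplotypes(x, y))


class TestLdDecay:
    def test_perfect_ld_pairs_in_first_bin(self):
        x = np.array([1] * 4 + [0] * 4, dtype=np.int8)
        hm = _matrix(np.stack([x, x, x]), positions=[100, 400, 800])
        panel = PopulationPanel({f"s{k}": "P" for k in range(4)})
        mids, means = ld_decay_curve(hm, panel, "P", max_dist=5000, bin_width=1000)
        assert means[0] == pytest.approx(1.0)
        assert np.isnan(means[1:]).all()

    def test_haplotype_shuffle_invariance(self, sweep_sim):
        hm, panel = sweep_sim.hm, sweep_sim.panel
        pop = panel.populations()[0]
        mids, means = ld_decay_curve(hm, panel, pop, max_dist=50_000)
        rng = np.random.default_rng(0)
        perm = rng.permutation(hm.n_samples)
        cols = np.ravel([[2 * p, 2 * p + 1] for p in perm])
        hm2 = HaplotypeMatrix(
            chrom=hm.chrom,
            positions=hm.positions,
            ref_allele=hm.ref_allele,
            alt_allele=hm.alt_allele,
            ancestral=hm.ancestral,
            calls=hm.calls[:, cols],
            sample_ids=[hm.sample_ids[p] for p in perm],
        )
        _, means2 = ld_decay_curve(hm2, panel, pop, max_dist=50_000)
        np.testing.assert_allclose(means, means2, equal_nan=True)

    def test_decays_with_distance_on_recombining_data(self, neutral_sim):
        from scipy.stats import spearmanr

        hm, panel = neutral_sim.hm, neutral_sim.panel
        pop = panel.populations()[0]
        mids, means = ld_decay_curve(
            hm, panel, pop, max_dist=150_000, bin_width=5_000
        )
        ok = ~np.isnan(means)
        rho, _ = spearmanr(mids[ok], means[ok])
        assert rho < 0

    def test_needs_two_variants(self):
        hm = _matrix(np.zeros((1, 4)))
        panel = PopulationPanel({"s0": "P", "s1": "P"})
        with pytest.raises(ValueError):
            ld_decay_curve(hm, panel, "P")
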