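"""Genome-verification tests: mapping, coverage, Welch test."""

import math

import numpy as np
import pytest

from hgtscan import align as hal
from hgtscan import verify
from hgtscan.synthetic import random_dna, simulate_reads


# ---------------------------------------------------------------------------
# brute-force affine-gap Smith-Waterman oracle (Gotoh, explicit loops)
# ---------------------------------------------------------------------------

def sw_oracle(q, s, match=1, mismatch=-2, gap_open=5, gap_extend=2):
    n, m = len(q), len(s)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            sub = match if q[i - 1] == s[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def test_nucleotide_alignment_matches_dp_oracle():
    rng = np.random.default_rng(12)
    for k in range(8):
        # mix of related and unrelated pairs
        a = random_dna(rng, int(rng.integers(80, 300)))
        if k % 2 == 0:
            b = random_dna(rng, 100) + a[10:200] + random_dna(rng, 80)
        else:
            b = random_dna(rng, int(rng.integers(80, 300)))
        hit = hal.nucleotide_local_align(a, b)
        want = sw_oracle(a, b)
        got = hit.score if hit else 0
        assert got == want, k


def test_protein_alignment_matches_dp_oracle():
    import biotite.sequence.align as ba
    mtx = ba.SubstitutionMatrix.std_protein_matrix()
    alpha = "".join(mtx.get_alphabet1())
    score = mtx.score_matrix()
    idx = {c: i for i, c in enumerate(alpha)}

    def sw_protein(q, s):
        NEG = -10**9
        n, m = len(q), len(s)
        H = [[0] * (m + 1) for _ in range(n + 1)]
        E = [[NEG] * (m + 1) for _ in range(n + 1)]
        F = [[NEG] * (m + 1) for _ in range(n + 1)]
        best = 0
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                E[i][j] = max(H[i][j - 1] - 11, E[i][j - 1] - 1)
                F[i][j] = max(H[i - 1][j] - 11, F[i - 1][j] - 1)
                sub = score[idx[q[i - 1]], idx[s[j - 1]]]
                H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
                best = max(best, H[i][j])
        return best

    rng = np.random.default_rng(3)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for k in range(6):
        a = "".join(rng.choice(aas, size=int(rng.integers(40, 150))))
        if k % 2 == 0:
            b = "".join(rng.choice(aas, size=20)) + a[5:90]
        else:
            b = "".join(rng.choice(aas, size=int(rng.integers(40, 150))))
        hit = hal.protein_local_align(a, b)
        want = sw_protein(a, b)
        got = hit.score if hit else 0
        assert got == want, k


# ---------------------------------------------------------------------------
# contig mapping
# ---------------------------------------------------------------------------

def test_exact_substring_maps_at_full_identity():
    rng = np.random.default_rng(1)
    contig = random_dna(rng, 3000)
    cand = contig[500:1300]
    hits = verify.map_to_contigs({"c1": cand}, {"ctg1": contig})
    assert hits and hits[0].percent_identity == 100.0
    assert hits[0].s_start == 500 and hits[0].s_end == 1300


def test_reverse_strand_candidate_maps():
    rng = np.random.default_rng(2)
    contig = random_dna(rng, 2000)
    cand = hal.revcomp(contig[300:900])
    hits = verify.map_to_contigs({"c1": cand}, {"ctg1": contig})
    assert hits and hits[0].strand == "-"
    assert hits[0].percent_identity == 100.0


def test_low_identity_candidate_rejected():
    rng = np.random.default_rng(3)
    contig = random_dna(rng, 2000)
    cand = list(contig[400:1000])
    flip = rng.choice(len(cand), size=len(cand) // 5, replace=False)  # 80% id
    for i in flip:
        cand[i] = "ACGT"[("ACGT".index(cand[i]) + 1) % 4]
    hits = verify.map_to_contigs({"c1": "".join(cand)}, {"ctg1": contig})
    assert hits == []


def test_empty_contig_set_errors():
    with pytest.raises(ValueError):
        verify.map_to_contigs({"c": "ACGT"}, {})


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def test_no_reads_zero_depth():
    profiles = verify.compute_coverage({}, {"c": "ACGT" * 100})
    assert all(p.depth == 0 for p in profiles.values())


def test_simulated_depth_recovered():
    rng = np.random.default_rng(5)
    contig = random_dna(rng, 10_000)
    reads = simulate_reads({"c": contig}, depth=40, read_length=100, seed=1)
    assert len(reads) == 4000
    profiles = verify.compute_coverage(reads, {"c": contig})
    assert profiles["c"].depth == pytest.approx(40.0, rel=0.03)


def test_three_mismatch_read_unmapped():
    rng = np.random.default_rng(6)
    contig = random_dna(rng, 1000)
    read = list(contig[100:200])
    for i in (10, 50, 90):
        read[i] = "ACGT"[("ACGT".index(read[i]) + 1) % 4]
    profiles = verify.compute_coverage({"r": "".join(read)}, {"c": contig})
    assert profiles["c"].aligned_reads == 0


def test_two_mismatch_read_maps():
    rng = np.random.default_rng(7)
    contig = random_dna(rng, 1000)
    read = list(contig[100:200])
    for i in (60, 90):
        read[i] = "ACGT"[("ACGT".index(read[i]) + 1) % 4]
    profiles = verify.compute_coverage({"r": "".join(read)}, {"c": contig})
    assert profiles["c"].aligned_reads == 1


def test_coverage_conservation():
    rng = np.random.default_rng(8)
    contigs = {f"c{i}": random_dna(rng, 2000) for i in range(3)}
    reads = simulate_reads(contigs, depth=5, read_length=80, seed=2)
    profiles = verify.compute_coverage(reads, contigs)
    total_aligned = sum(p.aligned_bases for p in profiles.values())
    assert sum(p.depth * p.length for p in profiles.values()) == pytest.approx(
        total_aligned, abs=1e-9)


def test_depth_override_ratio_recovered():
    rng = np.random.default_rng(9)
    contigs = {"hi": random_dna(rng, 8000), "lo": random_dna(rng, 8000)}
    reads = simulate_reads(contigs, depth=42, read_length=100, seed=3,
                           depth_overrides={"hi": 88})
    profiles = verify.compute_coverage(reads, contigs)
    ratio = profiles["hi"].depth / profiles["lo"].depth
    assert ratio == pytest.approx(88 / 42, rel=0.1)


def test_read_longer_than_contig_errors():
    with pytest.raises(ValueError):
        simulate_reads({"c": "ACGTACGT"}, depth=5, read_length=100, seed=0)


def test_reads_deterministic():
    rng = np.random.default_rng(10)
    contigs = {"c": random_dna(rng, 3000)}
    r1 = simulate_reads(contigs, depth=10, read_length=50, seed=4)
    r2 = simulate_reads(contigs, depth=10, read_length=50, seed=4)
    assert r1 == r2


# ---------------------------------------------------------------------------
# Welch test / coverage bias
# ---------------------------------------------------------------------------

def test_welch_closed_form_three_vs_three():
    x = [1.0, 2.0, 3.0]
    y = [2.0, 4.0, 9.0]
    t, df, p = verify.welch_t_test(x, y)
    # direct formula evaluation
    mx, my = 2.0, 5.0
    vx = sum((v - mx) ** 2 for v in x) / 2
    vy = sum((v - my) ** 2 for v in y) / 2
    se2 = vx / 3 + vy / 3
    t_ref = (mx - my) / math.sqrt(se2)
    df_ref = se2 ** 2 / ((vx / 3) ** 2 / 2 + (vy / 3) ** 2 / 2)
    from scipy import stats
    p_ref = 2 * stats.t.sf(abs(t_ref), df_ref)
    assert t == pytest.approx(t_ref, abs=1e-9)
    assert df == pytest.approx(df_ref, abs=1e-9)
    assert p == pytest.approx(p_ref, abs=1e-9)


def test_identical_groups_p_one():
    res = verify.coverage_bias_test([40.0, 40.0, 40.0],
                                    [40.0] * 50, n_background=10, seed=1)
    assert res.t_statistic == 0.0
    assert res.p_value == 1.0
    assert res.verdict == "consistent"


def test_doubled_depth_detected():
    rng = np.random.default_rng(11)
    pool = rng.normal(40, 4, size=2000)
    target = rng.normal(80, 6, size=14)
    res = verify.coverage_bias_test(target, pool, n_background=1000, seed=2)
    assert res.verdict == "biased"
    assert res.p_value < 1e-6


def test_null_calibration_small():
    rng = np.random.default_rng(12)
    rejections = 0
    n_rep = 300
    for _ in range(n_rep):
        pool = rng.normal(40, 4, size=1200)
        target = rng.normal(40, 4, size=14)
        res = verify.coverage_bias_test(target, pool, n_background=1000,
                                        seed=int(rng.integers(1 << 30)))
        rejections += res.verdict == "biased"
    assert 0.01 <= rejections / n_rep <= 0.10


def test_n_background_exceeds_pool_errors():
    with pytest.raises(ValueError):
        verify.coverage_bias_test([1.0, 2.0], [1.0] * 5, n_background=10)


# ---------------------------------------------------------------------------
# mito screen
# ---------------------------------------------------------------------------

def test_mito_screen_flags_unrelated_as_clean():
    rng = np.random.default_rng(13)
    mito = random_dna(rng, 3000)
    cands = {"c1": random_dna(rng, 600), "c2": random_dna(rng, 600)}
    res = verify.mito_screen(cands, mito)
    assert res == {"c1": [], "c2": []}


def test_mito_screen_detects_numt():
    rng = np.random.default_rng(14)
    mito = random_dna(rng, 3000)
    res = verify.mito_screen({"numt": mito[1000:1700]}, mito)
    assert len(res["numt"]) == 1
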