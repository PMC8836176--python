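"""Weighted local alignment and hybridization mfe versus brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import oracle_best_alignment, oracle_min_energy, oracle_structure_energy
from spongescan.duplex import (
    AlignmentParams,
    DuplexError,
    DuplexHit,
    EnergyParams,
    _gotoh_best,
    duplex_energy,
    filter_duplex_pairs,
    hybrid_mfe,
    miranda_align,
)
from spongescan.seqcore import Transcript, reverse_complement

AP = AlignmentParams.reference()
EP = EnergyParams.reference()


def _rand_rna(rng, lo, hi):
    return "".join(rng.choice(list("ACGU"), size=rng.integers(lo, hi + 1)))


# ------------------------------------------------------- alignment program

def test_reference_alignment_params_loaded():
    assert AP.match_score == 5.0 and AP.seed_scale == 4.0
    assert AP.seed_window == (2, 8)


def test_perfect_complement_toy_scores_len_times_match():
    """8-nt perfect duplex, no seed weighting: score is 8 * match."""
    params = AlignmentParams(seed_scale=1.0)
    m = "ACGUACGU"
    t = reverse_complement(m)
    res = _gotoh_best(m, t, params)
    assert res[0] == pytest.approx(8 * params.match_score)
    assert res[0] == pytest.approx(oracle_best_alignment(m, t, params))


def test_unpairable_sequences_produce_no_hit():
    m = Transcript("m", "miRNA", "A" * 21)
    t = Transcript("t", "lncRNA", "A" * 30)
    assert miranda_align(m, t, AP) == []


def test_degenerate_params_rejected():
    with pytest.raises(DuplexError, match="match_score"):
        AlignmentParams(match_score=-1.0)


def test_alignment_monotone_in_match_score_and_gap_penalty():
    rng = np.random.default_rng(12)
    for _ in range(20):
        m = _rand_rna(rng, 8, 12)
        t = _rand_rna(rng, 15, 25)
        base = _gotoh_best(m, t, AP)
        up = _gotoh_best(m, t, AlignmentParams(match_score=AP.match_score + 2))
        harsher = _gotoh_best(m, t, AlignmentParams(gap_open=-18, gap_extend=-8))
        s0 = base[0] if base else 0.0
        assert (up[0] if up else 0.0) >= s0
        assert (harsher[0] if harsher else 0.0) <= s0


def test_alignment_matches_enumeration_on_random_instances():
    rng = np.random.default_rng(101)
    for _ in range(60):
        m = _rand_rna(rng, 5, 7)
        t = _rand_rna(rng, 6, 9)
        res = _gotoh_best(m, t, AP)
        assert (res[0] if res else 0.0) == pytest.approx(oracle_best_alignment(m, t, AP))


def test_multiple_sites_are_non_overlapping_and_sorted():
    """Two copies of the perfect complement yield two disjoint hits,
    best-first, with equal scores resolved to the smaller start."""
    mseq = "UCCUGUACUGAGCUGCCCCGAG"
    m = Transcript("m", "miRNA", mseq)
    site = reverse_complement(mseq)
    t = Transcript("t", "lncRNA", "AUAU" + site + "CGCAUAUGCAU" + site + "AUAU")
    hits = miranda_align(m, t, AP)
    assert len(hits) == 2
    (a, b) = hits
    assert a.align_score == b.align_score
    assert a.target_start < b.target_start  # tie -> smaller start first
    assert a.target_end < b.target_start or b.target_end < a.target_start


# ---------------------------------------------------------- energy program

def test_reference_energy_params_loaded():
    assert EP.duplex_init == pytest.approx(4.10)
    assert EP.stack[1][1] == pytest.approx(-3.40)  # 5'GC/3'CG, strongest stack


def test_polyA_duplex_returns_sentinel():
    m = Transcript("m", "miRNA", "A" * 20)
    t = Transcript("t", "lncRNA", "A" * 20)
    assert hybrid_mfe(m, t, EP) is None


def test_perfect_helix_energy_is_init_plus_stacks():
    """GCGCG against its exact complement: initiation + the four
    tabulated stack terms, confirmed by exhaustive enumeration."""
    m = "GCGCG"
    t = reverse_complement(m)
    hit = hybrid_mfe(Transcript("m", "miRNA", m), Transcript("t", "lncRNA", t), EP)
    # pairs alternate GC/CG: stacks GC-GC, CG-CG, GC-GC, CG-CG in mirror convention
    expected = EP.duplex_init + 2 * EP.stack[1][1] + 2 * EP.stack[0][0]
    assert hit.mfe == pytest.approx(expected)
    assert hit.mfe == pytest.approx(oracle_min_energy(m, t, EP))


def test_energy_matches_enumeration_on_random_instances():
    rng = np.random.default_rng(202)
    for _ in range(60):
        m = _rand_rna(rng, 5, 8)
        t = _rand_rna(rng, 6, 10)
        hit = hybrid_mfe(Transcript("m", "miRNA", m), Transcript("t", "lncRNA", t), EP)
        dp = hit.mfe if hit is not None else float("inf")
        assert dp == pytest.approx(oracle_min_energy(m, t, EP))


def test_mfe_never_beats_an_explicit_certificate():
    """The DP optimum lower-bounds the energy of any explicitly
    constructed structure (random chains of canonical pairs)."""
    rng = np.random.default_rng(303)
    for _ in range(30):
        m = _rand_rna(rng, 8, 12)
        t = _rand_rna(rng, 10, 16)
        hit = hybrid_mfe(Transcript("m", "miRNA", m), Transcript("t", "lncRNA", t), EP)
        dp = hit.mfe if hit is not None else float("inf")
        cells = [(i + 1, j + 1) for i in range(len(m)) for j in range(len(t))
                 if (m[i] + t[j]) in {"AU", "UA", "GC", "CG", "GU", "UG"}]
        for _ in range(20):
            rng.shuffle(cells)
            chain, last = [], None
            for (i, j) in sorted(cells[: rng.integers(2, 8)]):
                if last is None or (i > last[0] and j < last[1]):
                    chain.append((i, j))
                    last = (i, j)
            cert = duplex_energy(m, t, chain, EP)
            assert dp <= cert + 1e-9
            assert cert == pytest.approx(
                oracle_structure_energy(m, t, [(i - 1, j - 1) for i, j in chain], EP))


def test_mfe_agrees_with_full_nearest_neighbor_model_on_perfect_helix():
    """On a perfect-complement duplex (no loops), the simplified model
    coincides with ViennaRNA's RNAduplex under the same 1999 tables."""
    import shutil
    import subprocess

    if shutil.which("RNAduplex") is None:
        pytest.skip("RNAduplex not on PATH")
    m = "GGCAUCGCAGG"
    t = reverse_complement(m)
    hit = hybrid_mfe(Transcript("m", "miRNA", m), Transcript("t", "lncRNA", t), EP)
    out = subprocess.run(
        ["RNAduplex", "-P", "/opt/conda/envs/bio/share/ViennaRNA/rna_turner1999.par"],
        input=f"{m}\n{t}\n", capture_output=True, text=True, check=True,
    ).stdout
    vienna = float(out.rsplit("(", 1)[1].rstrip(")\n "))
    assert hit.mfe == pytest.approx(vienna, abs=0.01)


def test_site_mutation_weakens_both_scores(linc, linc_mut, mir486):
    """The binding-site point mutation raises the duplex energy and
    lowers the alignment score relative to wild type."""
    wt_hits = miranda_align(mir486, linc, AP)
    mut_hits = miranda_align(mir486, linc_mut, AP)
    wt_best = wt_hits[0].align_score if wt_hits else 0.0
    mut_best = mut_hits[0].align_score if mut_hits else 0.0
    assert mut_best < wt_best
    wt_e = hybrid_mfe(mir486, linc, EP).mfe
    mut_e = hybrid_mfe(mir486, linc_mut, EP).mfe
    assert mut_e > wt_e


# ----------------------------------------------------------- joint filter

def _hit(score, mfe):
    return DuplexHit("m", "t", align_score=score, mfe=mfe)


def test_filter_keeps_strictly_passing_pairs_in_order():
    hits = [_hit(158.0, -38.4), _hit(150.0, -40.0), _hit(170.0, -30.0), _hit(160.0, -31.0)]
    kept = filter_duplex_pairs(hits)
    assert [h.align_score for h in kept] == [158.0, 160.0]


def test_filter_requires_both_scores():
    with pytest.raises(DuplexError, match="m:t"):
        filter_duplex_pairs([DuplexHit("m", "t", align_score=160.0)])


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    m=st.text(alphabet="ACGU", min_size=5, max_size=7),
    t=st.text(alphabet="ACGU", min_size=6, max_size=9),
)
def test_property_both_programs_match_enumeration(m, t):
    res = _gotoh_best(m, t, AP)
    assert (res[0] if res else 0.0) == pytest.approx(oracle_best_alignment(m, t, AP))
    hit = hybrid_mfe(Transcript("m", "miRNA", m), Transcript("t", "lncRNA", t), EP)
    dp = hit.mfe if hit is not None else float("inf")
    assert dp == pytest.approx(oracle_min_energy(m, t, EP))
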