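"""Super-enhancer overlap and allele-specific motif-disruption scoring."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riskcascade import (
    GenomicInterval, Pwm, RegulatoryError, filter_by_motif, overlap_superenhancers,
    read_jaspar, score_allele, score_motif_disruption, write_jaspar,
)
from riskcascade.regulatory import reverse_complement

BASES = "ACGT"


def variants_frame(positions, chrom="chr1"):
    return pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(len(positions))],
        "chrom": chrom, "pos": positions, "ref": "A", "alt": "G",
    })


def test_overlap_boundary_coordinates():
    iv = [GenomicInterval("chr1", 99, 100, "se1")]
    inside = overlap_superenhancers(variants_frame([100]), iv)
    assert len(inside) == 1 and inside.iloc[0]["se_intervals"] == "se1"
    # end coordinate is exclusive
    outside = overlap_superenhancers(variants_frame([101]), iv)
    assert outside.empty


def test_overlap_matches_brute_force_scan():
    rng = np.random.default_rng(21)
    chroms = [f"chr{c}" for c in range(1, 4)]
    variants = pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(1000)],
        "chrom": rng.choice(chroms, 1000),
        "pos": rng.integers(1, 5000, 1000),
        "ref": "A", "alt": "G",
    })
    intervals = []
    for k in range(200):
        start = int(rng.integers(0, 4900))
        intervals.append(GenomicInterval(str(rng.choice(chroms)), start,
                                         start + int(rng.integers(1, 120)), f"iv{k}"))
    got = overlap_superenhancers(variants, intervals)
    expected = set()
    for row in variants.itertuples():
        for iv in intervals:
            if iv.chrom == row.chrom and iv.start <= row.pos - 1 < iv.end:
                expected.add(row.rsid)
                break
    assert set(got["rsid"]) == expected


def test_invalid_interval_raises():
    with pytest.raises(RegulatoryError):
        GenomicInterval("chr1", 100, 100)
    with pytest.raises(RegulatoryError):
        GenomicInterval("chr1", -1, 100)


def test_single_position_pwm_log_odds():
    probs = np.array([[0.97, 0.01, 0.01, 0.01]])
    pwm = Pwm("m", probs, pseudocount=0.001)
    expected = np.log2(((0.97 + 0.001) / 1.004) / 0.25)
    assert score_allele(pwm, "A") == pytest.approx(expected, abs=1e-12)


def test_uniform_pwm_scores_zero():
    pwm = Pwm("u", np.full((5, 4), 0.25))
    assert score_allele(pwm, "ACGTA") == pytest.approx(0.0, abs=1e-12)


@settings(max_examples=60, deadline=None)
@given(data=st.data())
def test_strand_symmetry(data):
    length = data.draw(st.integers(2, 8))
    raw = np.array(data.draw(st.lists(
        st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
        min_size=length, max_size=length)))
    probs = raw / raw.sum(axis=1, keepdims=True)
    pwm = Pwm("m", probs)
    window = "".join(data.draw(st.sampled_from(BASES)) for _ in range(length))
    fwd = score_allele(pwm, window)
    rev = score_allele(pwm.reverse_complement(), reverse_complement(window))
    assert fwd == pytest.approx(rev, abs=1e-9)


def test_score_allele_rejects_bad_windows():
    pwm = Pwm("m", np.full((3, 4), 0.25))
    with pytest.raises(RegulatoryError):
        score_allele(pwm, "ANT")
    with pytest.raises(RegulatoryError):
        score_allele(pwm, "ACGT")  # wrong length


def strong_pwm(consensus="ACGTA"):
    probs = np.full((len(consensus), 4), 0.01)
    for i, b in enumerate(consensus):
        probs[i, BASES.index(b)] = 0.97
    return Pwm("strong", probs)


def test_disruption_delta_equals_window_score_difference():
    pwm = strong_pwm("ACGTA")
    context = "TT" + "ACGTA" + "TT"  # variant at center = motif position 2 (G)
    call = score_motif_disruption(pwm, context, ref="G", alt="T", rsid="rs1")
    assert call is not None
    ref_s = score_allele(pwm, "ACGTA")
    alt_s = score_allele(pwm, "ACTTA")
    # the same disruption magnitude is visible on both strands (the reverse
    # complement of the consensus also sits in this context), so only the
    # magnitude is pinned down
    assert call.delta == pytest.approx(ref_s - alt_s, abs=1e-12)
    assert call.delta > 0


def test_symmetric_alleles_give_zero_delta():
    # palindromic-probability position: swapping G->C scores identically
    probs = np.full((3, 4), 0.01)
    probs[:, 1] = 0.485  # C
    probs[:, 2] = 0.485  # G
    probs /= probs.sum(axis=1, keepdims=True)
    pwm = Pwm("sym", probs)
    call = score_motif_disruption(pwm, "GGGGG", ref="G", alt="C", rsid="rs1",
                                  match_threshold=-100)
    assert call is not None
    assert call.delta == pytest.approx(0.0, abs=1e-12)


def brute_force_calls(pwm, context, ref, alt, match_threshold):
    """Every qualifying (strand, offset) window with its ref/alt scores."""
    center = len(context) // 2
    alt_ctx = context[:center] + alt + context[center + 1:]
    L = len(pwm)
    calls = {}
    for start in range(max(0, center - L + 1), min(center, len(context) - L) + 1):
        for strand in "+-":
            w_ref, w_alt = context[start:start + L], alt_ctx[start:start + L]
            if strand == "-":
                w_ref, w_alt = reverse_complement(w_ref), reverse_complement(w_alt)
            rs, as_ = score_allele(pwm, w_ref), score_allele(pwm, w_alt)
            if max(rs, as_) >= match_threshold:
                calls[(strand, start - center)] = (rs, as_)
    return calls


def test_best_call_matches_exhaustive_enumeration():
    # |delta| ties can occur (the same single-position difference can appear
    # on both strands), so the check is: the returned call attains the
    # maximal |delta| over the exhaustive enumeration and reports the exact
    # scores of its own window.
    rng = np.random.default_rng(31)
    n_defined = 0
    for trial in range(30):
        raw = rng.uniform(0.05, 1, size=(9, 4))
        pwm = Pwm(f"m{trial}", raw / raw.sum(axis=1, keepdims=True))
        context = "".join(rng.choice(list(BASES), size=21))
        ref = context[10]
        alt = rng.choice([b for b in BASES if b != ref])
        thr = 0.3 * pwm.max_score()
        call = score_motif_disruption(pwm, context, ref, alt, match_threshold=thr)
        expect = brute_force_calls(pwm, context, ref, alt, thr)
        if not expect:
            assert call is None
            continue
        n_defined += 1
        best_delta = max(abs(rs - as_) for rs, as_ in expect.values())
        assert call is not None
        assert abs(call.delta) == pytest.approx(best_delta, abs=1e-9)
        rs, as_ = expect[(call.strand, call.offset)]
        assert call.ref_score == pytest.approx(rs, abs=1e-9)
        assert call.alt_score == pytest.approx(as_, abs=1e-9)
    assert n_defined >= 5  # the exercise is non-vacuous


def test_ref_mismatch_and_indels():
    pwm = strong_pwm()
    with pytest.raises(RegulatoryError, match="rsX"):
        score_motif_disruption(pwm, "AAAAAAAAA", ref="G", alt="T", rsid="rsX")
    with pytest.raises(RegulatoryError, match="rsY"):
        score_motif_disruption(pwm, "AAAAAAAAA", ref="A", alt="AT", rsid="rsY")


def test_filter_retains_planted_motif_variant_only():
    rng = np.random.default_rng(41)
    pwm = strong_pwm("ACGTACGTA")
    consensus = "ACGTACGTA"
    hw = 10
    planted_ctx = ("T" * (hw - 4)) + consensus + ("T" * (hw - 4))
    random_ctx = "".join(rng.choice(list(BASES), size=2 * hw + 1))
    random_ctx = random_ctx[:hw] + "A" + random_ctx[hw + 1:]
    variants = pd.DataFrame({
        "rsid": ["rsPlanted", "rsRandom"],
        "chrom": "chr1", "pos": [100, 200],
        "ref": [consensus[4], "A"], "alt": ["C", "C"],
    })
    contexts = {"rsPlanted": planted_ctx, "rsRandom": random_ctx}
    retained, calls, stats = filter_by_motif(variants, [pwm], contexts)
    assert list(retained["rsid"]) == ["rsPlanted"]
    assert (calls["rsid"] == "rsPlanted").all()
    assert stats.n_retained == 1


def test_filter_edge_cases():
    variants = pd.DataFrame({
        "rsid": ["rs1", "rs2", "rs3", "rs4"],
        "chrom": "chr1", "pos": [100, 200, 300, 400],
        "ref": ["A", "AT", "A", "A"], "alt": ["G", "A", "G", "G"],
    })
    contexts = {"rs1": "TTTTATTTT", "rs4": "TTTTATTTT"}  # rs3 has no context
    # empty PWM collection keeps nothing
    retained, calls, stats = filter_by_motif(variants, [], contexts)
    assert retained.empty
    assert stats.n_indels_skipped == 1
    # vacuous thresholds keep every SNV with a context
    pwm = Pwm("u", np.full((3, 4), 0.25))
    retained, _, stats = filter_by_motif(
        variants, [pwm], contexts, strong_threshold=-np.inf, match_frac=0.0)
    assert list(retained["rsid"]) == ["rs1", "rs4"]
    assert stats.n_missing_context == 1


def test_jaspar_roundtrip(tmp_path):
    rng = np.random.default_rng(51)
    raw = rng.uniform(0.05, 1, size=(7, 4))
    pwms = [Pwm("MA0001.1", raw / raw.sum(axis=1, keepdims=True)),
            Pwm("MA0002.1", np.full((4, 4), 0.25))]
    path = tmp_path / "m.jaspar"
    write_jaspar(pwms, path)
    back = read_jaspar(path)
    assert [p.pwm_id for p in back] == ["MA0001.1", "MA0002.1"]
    np.testing.assert_allclose(back[0].probs, pwms[0].probs, atol=1e-5)
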