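"""Regulatory filters: super-enhancer overlap and allele-specific motif scoring.

Variants are first restricted to those falling inside super-enhancer
intervals (BED, 0-based half-open; variant positions are 1-based), then to
those whose alternate allele strongly disrupts a transcription-factor
binding motif.  Motif disruption is scored as the difference in best
log-odds PWM score between the reference and alternate sequence over every
window covering the variant on both strands.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class RegulatoryError(ValueError):
    """Raised on malformed intervals, PWMs, or sequence contexts."""


# ---------------------------------------------------------------------------
# Super-enhancer intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A super-enhancer region; start is 0-based inclusive, end exclusive."""
    chrom: str
    start: int
    end: int
    interval_id: str = ""
    cell_type: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise RegulatoryError(
                f"invalid interval {self.interval_id or ''} {self.chrom}:{self.start}-{self.end}"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (name in column 4, cell type in column 5)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise RegulatoryError(f"{path}:{i + 1}: expected >= 3 BED columns")
            out.append(GenomicInterval(
                chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                interval_id=parts[3] if len(parts) > 3 else f"iv{i + 1}",
                cell_type=parts[4] if len(parts) > 4 else "",
            ))
    return out


def overlap_superenhancers(
    variants: pd.DataFrame, intervals: list[GenomicInterval]
) -> pd.DataFrame:
    """Subset variants to those inside a super-enhancer interval.

    A variant at 1-based position ``pos`` overlaps an interval when
    ``pos - 1`` lies in ``[start, end)`` on the same chromosome.  All
    matching interval IDs are recorded (comma-joined, sorted) in an
    ``se_intervals`` column.  An interval tree is used per chromosome;
    results are identical to a brute-force scan.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.interval_id)
    hits = []
    for row in variants.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        found = tree[row.pos - 1]
        if found:
            hits.append((row.Index, ",".join(sorted(h.data for h in found))))
    if not hits:
        out = variants.iloc[0:0].copy()
        out["se_intervals"] = pd.Series(dtype=str)
        return out
    idx, ann = zip(*hits)
    out = variants.loc[list(idx)].copy()
    out["se_intervals"] = list(ann)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------

@dataclass
class Pwm:
    """Per-position base-probability model of a TF binding motif.

    ``probs`` has shape (length, 4) in A,C,G,T order; each row sums to 1.
    Scoring adds a pseudocount and renormalizes, then takes log2 odds
    against the background base frequencies.
    """
    pwm_id: str
    probs: np.ndarray
    pseudocount: float = 0.001
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise RegulatoryError(f"{self.pwm_id}: probs must be (length, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise RegulatoryError(f"{self.pwm_id}: position probabilities must sum to 1")
        if self.pseudocount <= 0:
            raise RegulatoryError(f"{self.pwm_id}: pseudocount must be > 0")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise RegulatoryError(f"{self.pwm_id}: background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(length, 4) matrix of log2((p + pc)/(1 + 4 pc) / background)."""
        adj = (self.probs + self.pseudocount) / (1 + 4 * self.pseudocount)
        return np.log2(adj / self.background)

    def max_score(self) -> float:
        """Best achievable log-odds score (consensus sequence)."""
        return float(self.log_odds.max(axis=1).sum())

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            pwm_id=self.pwm_id,
            probs=self.probs[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
        )

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


def score_allele(pwm: Pwm, window: str) -> float:
    """Log-odds score of one sequence window against a PWM.

    The window must match the PWM length and contain only A/C/G/T.
    """
    window = window.upper()
    if len(window) != len(pwm):
        raise RegulatoryError(
            f"window length {len(window)} != PWM length {len(pwm)} for {pwm.pwm_id}"
        )
    try:
        cols = [_BASE_INDEX[b] for b in window]
    except KeyError as exc:
        raise RegulatoryError(f"window contains non-ACGT base {exc.args[0]!r}") from None
    lo = pwm.log_odds
    return float(lo[np.arange(len(pwm)), cols].sum())


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def read_jaspar(path: str | Path) -> list[Pwm]:
    """Read a JASPAR-style text PWM collection.

    Records start with a ``>`` header; the four following lines give A, C,
    G, T counts (or probabilities), optionally in the bracketed
    ``A [ 1 2 3 ]`` form.  Counts are column-normalized to probabilities.
    """
    pwms: list[Pwm] = []
    header = None
    rows: list[list[float]] = []

    def flush():
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise RegulatoryError(f"{header}: expected 4 base rows, got {len(rows)}")
        mat = np.array(rows, dtype=float).T  # positions x bases
        colsums = mat.sum(axis=1, keepdims=True)
        if (colsums <= 0).any():
            raise RegulatoryError(f"{header}: zero column sum")
        pwms.append(Pwm(pwm_id=header, probs=mat / colsums))
        header, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
            else:
                body = line
                if body[0] in "ACGTacgt" and ("[" in body or body[1:2].isspace()):
                    body = body[1:]
                body = body.replace("[", " ").replace("]", " ")
                rows.append([float(x) for x in body.split()])
    flush()
    return pwms


def write_jaspar(pwms: list[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.pwm_id}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v:.6f}" for v in p.probs[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


def read_contexts_fasta(path: str | Path) -> dict[str, str]:
    """Per-variant sequence contexts keyed by rsID (variant at the center)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Allele-specific motif disruption
# ---------------------------------------------------------------------------

@dataclass
class MotifDisruptionCall:
    rsid: str
    pwm_id: str
    strand: str               # '+' or '-'
    offset: int               # window start relative to the variant (<= 0)
    ref_score: float
    alt_score: float
    delta: float              # ref_score - alt_score
    is_strong: bool = False


def score_motif_disruption(
    pwm: Pwm,
    context: str,
    ref: str,
    alt: str,
    rsid: str = "",
    match_threshold: float | None = None,
    match_frac: float = 0.8,
) -> MotifDisruptionCall | None:
    """Best allele-specific disruption call for one PWM at one variant.

    Every window covering the central base is scored on both strands for the
    reference and alternate sequence; among windows where the better allele
    reaches ``match_threshold`` (default: ``match_frac`` of the PWM's maximum
    achievable score) the call maximizing ``|ref_score - alt_score|`` is
    returned, or None when no window qualifies.
    """
    context = context.upper()
    if len(context) % 2 != 1:
        raise RegulatoryError(f"{rsid}: context length must be odd (variant centered)")
    center = len(context) // 2
    if len(ref) != 1 or len(alt) != 1:
        raise RegulatoryError(f"{rsid}: not a single-nucleotide variant")
    if context[center] != ref.upper():
        raise RegulatoryError(
            f"{rsid}: reference allele {ref!r} does not match context base "
            f"{context[center]!r}"
        )
    L = len(pwm)
    if match_threshold is None:
        match_threshold = match_frac * pwm.max_score()
    alt_context = context[:center] + alt.upper() + context[center + 1:]
    rc_pwm = pwm.reverse_complement()

    best: MotifDisruptionCall | None = None
    for start in range(max(0, center - L + 1), min(center, len(context) - L) + 1):
        ref_win = context[start:start + L]
        alt_win = alt_context[start:start + L]
        if "N" in ref_win or "N" in alt_win:
            continue
        for strand, mat in (("+", pwm), ("-", rc_pwm)):
            ref_s = score_allele(mat, ref_win)
            alt_s = score_allele(mat, alt_win)
            if max(ref_s, alt_s) < match_threshold:
                continue
            delta = ref_s - alt_s
            if best is None or abs(delta) > abs(best.delta):
                best = MotifDisruptionCall(
                    rsid=rsid, pwm_id=pwm.pwm_id, strand=strand,
                    offset=start - center, ref_score=ref_s, alt_score=alt_s,
                    delta=delta,
                )
    return best


@dataclass
class MotifFilterStats:
    n_variants: int = 0
    n_retained: int = 0
    n_indels_skipped: int = 0
    n_missing_context: int = 0
    n_disrupted_pwms: int = 0


def filter_by_motif(
    variants: pd.DataFrame,
    pwms: list[Pwm],
    contexts: dict[str, str],
    strong_threshold: float = 2.0,
    match_frac: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame, MotifFilterStats]:
    """Retain variants with at least one strong motif-disruption call.

    A call is strong when the better allele scores at least ``match_frac``
    of the PWM's maximum (it looks like a motif hit) and the allele score
    difference reaches ``strong_threshold`` bits.  Indels and variants
    without a sequence context are skipped with counted warnings.

    Returns (retained variants, table of all strong calls, statistics).
    """
    stats = MotifFilterStats(n_variants=len(variants))
    call_rows = []
    retained_idx = []
    for row in variants.itertuples():
        if len(str(row.ref)) != 1 or len(str(row.alt)) != 1:
            stats.n_indels_skipped += 1
            continue
        ctx = contexts.get(row.rsid)
        if ctx is None:
            stats.n_missing_context += 1
            log.warning("no sequence context for %s; variant dropped", row.rsid)
            continue
        strong = False
        for pwm in pwms:
            if len(pwm) > (len(ctx) + 1) // 2:
                continue  # context window too short for this motif
            call = score_motif_disruption(
                pwm, ctx, str(row.ref), str(row.alt), rsid=row.rsid,
                match_frac=match_frac,
            )
            if call is None:
                continue
            if abs(call.delta) >= strong_threshold:
                call.is_strong = True
                strong = True
                call_rows.append((
                    call.rsid, call.pwm_id, call.strand, call.offset,
                    call.ref_score, call.alt_score, call.delta,
                ))
        if strong:
            retained_idx.append(row.Index)
    calls = pd.DataFrame(
        call_rows,
        columns=["rsid", "pwm_id", "strand", "offset", "ref_score", "alt_score", "delta"],
    )
    retained = variants.loc[retained_idx].reset_index(drop=True)
    stats.n_retained = len(retained)
    stats.n_disrupted_pwms = calls["pwm_id"].nunique() if len(calls) else 0
    return retained, calls, stats


def write_variant_bed(variants: pd.DataFrame, path: str | Path, name: str = "disrupt_eQTL_SNPs") -> None:
    """BED track of retained variants (one 1-bp feature per variant)."""
    with open(path, "w") as fh:
        fh.write(f'track name="{name}"\n')
        ordered = variants.sort_values(["chrom", "pos"], kind="mergesort")
        for row in ordered.itertuples():
            fh.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{row.rsid}\n")
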