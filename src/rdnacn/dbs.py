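"""Per-read methylation calling from bisulfite amplicon reads.

Each sequenced molecule (epiallele) yields one read (or read pair) over the
promoter amplicon.  Processing per read:

1.  Bisulfite-aware ungapped semi-global alignment to the amplicon:
    against a reference C the read may show C (unconverted / methylated)
    or T (converted); both orientations are tried (mate 2 of a pair is the
    reverse complement of the converted top strand).  Reads failing an
    identity floor on non-cytosine columns are rejected as non-amplicon.
2.  Conversion QC: the fraction of non-CpG reference cytosines read as T
    estimates the molecule's bisulfite conversion rate; reads are kept
    only if it strictly exceeds the threshold (default 0.95).
3.  Allele call at the A/G variant site; only major-allele (G) reads are
    retained so sequence variants do not masquerade as methylation.
4.  CpG states at the 25 annotated sites: C = methylated, T =
    unmethylated, anything else ambiguous; reads with fewer than
    ``min_cpgs`` analyzable sites are rejected.

Retained reads are summarised per sample into 10 methylation bins of 10
percentage points.  The first bin is closed at 10% ([0, 10]) so that bin-0
membership coincides with the "hypomethylated, presumably active" rule
(methylation <= 10%); later bins are half-open (10, 20], ... (90, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import encode_seq, reverse_complement
from .reference import AmpliconReference, N_CPGS

_C = ord("C")
_T = ord("T")
_G = ord("G")
_A = ord("A")
_GAP = 0  # uncovered position in a merged consensus

BIN_EDGES = tuple(range(0, 101, 10))  # [0,10], (10,20], ..., (90,100]

REASONS = ("unmapped", "qc_insufficient", "low_conversion", "minor_allele",
           "variant_uncovered", "cpg_missing", "mate_conflict")


@dataclass
class Alignment:
    offset: int  # reference offset of read position 0
    reverse: bool  # True if the read aligned as its reverse complement
    identity: float  # identity over non-cytosine reference columns
    read_top: np.ndarray  # read bytes in top-strand orientation


@dataclass
class ReadCall:
    """Methylation call for one read (or merged pair)."""

    read_id: str
    allele: str  # "G" | "A" | "ambiguous"
    conversion_rate: float | None
    cpg_states: tuple[str, ...]  # per annotated CpG: "M" | "U" | "." (ambiguous/uncovered)
    pass_filters: bool
    reasons: tuple[str, ...] = ()

    @property
    def n_methylated(self) -> int:
        return sum(s == "M" for s in self.cpg_states)

    @property
    def n_analyzable(self) -> int:
        return sum(s in ("M", "U") for s in self.cpg_states)

    @property
    def methylation_pct(self) -> float:
        n = self.n_analyzable
        return 100.0 * self.n_methylated / n if n else float("nan")

    @property
    def bin_index(self) -> int:
        return methylation_bin(self.methylation_pct)


@dataclass
class MethylationProfile:
    """Per-sample summary of retained epiallele reads."""

    sample_id: str
    n_reads_total: int
    n_reads_retained: int
    rejection_reasons: dict[str, int]
    bin_fractions: np.ndarray  # length 10, sums to 1 when reads retained
    mean_methylation_pct: float
    no_data: bool = False

    @property
    def hypomethylated_fraction(self) -> float:
        """Fraction of retained reads with methylation <= 10% (bin 0)."""
        return float(self.bin_fractions[0])

    def to_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            "n_reads_total": self.n_reads_total,
            "n_reads_retained": self.n_reads_retained,
            "mean_methylation_pct": self.mean_methylation_pct,
            "hypomethylated_fraction": self.hypomethylated_fraction,
            "no_data": self.no_data,
        }
        for i, f in enumerate(self.bin_fractions):
            row[f"bin_{BIN_EDGES[i]}_{BIN_EDGES[i + 1]}"] = f
        for reason in REASONS:
            row[f"rejected_{reason}"] = self.rejection_reasons.get(reason, 0)
        return row


def methylation_bin(pct: float) -> int:
    """Bin index for a methylation percentage: [0,10] -> 0, (10,20] -> 1, ..."""
    if np.isnan(pct):
        return -1
    if pct <= 10:
        return 0
    return min(int(np.ceil(pct / 10.0)) - 1, 9)


# ---------------------------------------------------------------- alignment


def _align_batch(seqs: np.ndarray, ref: np.ndarray, identity_floor: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ungapped semi-global alignment of equal-length reads to the reference.

    Returns (offsets, reverse_flags, identities); offset = -1 for reads
    below the identity floor.  Scoring counts a column as a match when the
    bases agree, or when the reference has C and the read T (bisulfite
    conversion).  Identity is assessed on non-C reference columns only, so
    methylation state cannot affect mapping.
    """
    n, lr = seqs.shape
    L = ref.size
    if lr > L:
        raise ValueError("read longer than reference amplicon")
    n_off = L - lr + 1
    rc = np.empty_like(seqs)
    comp = np.full(256, ord("N"), dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    rc[:] = comp[seqs][:, ::-1]

    best_score = np.full(n, -1, dtype=np.int32)
    best_off = np.full(n, -1, dtype=np.int32)
    best_rev = np.zeros(n, dtype=bool)
    best_ident = np.zeros(n, dtype=float)

    for rev, mat in ((False, seqs), (True, rc)):
        for off in range(n_off):
            win = ref[off : off + lr]
            is_c = win == _C
            match = (mat == win) | (is_c & (mat == _T))
            score = match.sum(axis=1).astype(np.int32)
            non_c = ~is_c
            denom = int(non_c.sum())
            ident = (match & non_c).sum(axis=1) / denom if denom else np.ones(n)
            better = score > best_score
            best_score[better] = score[better]
            best_off[better] = off
            best_rev[better] = rev
            best_ident[better] = ident[better]
    best_off[best_ident < identity_floor] = -1
    return best_off, best_rev, best_ident


def align_to_amplicon(
    read_seq: str,
    ref: AmpliconReference,
    identity_floor: float = 0.80,
    min_length: int = 50,
) -> Alignment | None:
    """Align one read to the amplicon; ``None`` means rejected (unmapped)."""
    if len(read_seq) < min_length:
        return None
    enc = encode_seq(read_seq)[None, :]
    if enc.shape[1] > ref.length:
        return None
    off, rev, ident = _align_batch(enc, ref.encoded, identity_floor)
    if off[0] < 0:
        return None
    top = encode_seq(reverse_complement(read_seq)) if rev[0] else enc[0]
    return Alignment(offset=int(off[0]), reverse=bool(rev[0]), identity=float(ident[0]), read_top=np.asarray(top))


# ------------------------------------------------------------ per-read calls


def _consensus_from_alignments(alignments: Sequence[Alignment], L: int) -> np.ndarray:
    """Merge aligned mates into one reference-length consensus.

    Uncovered positions are 0; positions where mates disagree become 'N'
    (ambiguous) rather than trusting either mate.
    """
    cons = np.zeros(L, dtype=np.uint8)
    for aln in alignments:
        s, e = aln.offset, aln.offset + aln.read_top.size
        seg = cons[s:e]
        new = aln.read_top
        conflict = (seg != 0) & (seg != new)
        seg[seg == 0] = new[seg == 0]
        seg[conflict] = ord("N")
    return cons


def conversion_rate(consensus: np.ndarray, ref: AmpliconReference, min_non_cpg_c: int = 10) -> float | None:
    """Bisulfite conversion rate from non-CpG reference cytosines.

    rate = #T / (#T + #C) over covered non-CpG reference C positions; other
    bases (sequencing errors, N) carry no conversion evidence and are
    excluded.  ``None`` when fewer than ``min_non_cpg_c`` informative
    positions are covered.
    """
    pos = np.fromiter(ref.non_cpg_c_positions, dtype=int)
    bases = consensus[pos]
    n_t = int((bases == _T).sum())
    n_c = int((bases == _C).sum())
    if n_t + n_c < min_non_cpg_c:
        return None
    return n_t / (n_t + n_c)


def call_allele(consensus: np.ndarray, ref: AmpliconReference) -> str:
    """Call the A/G variant from the top-strand consensus.

    The variant site is not a cytosine on the top strand, so bisulfite
    conversion does not touch it; any base other than A or G (or no
    coverage) is ambiguous.
    """
    b = int(consensus[ref.variant_offset])
    if b == _G:
        return "G"
    if b == _A:
        return "A"
    return "ambiguous"


def cpg_states_from_consensus(consensus: np.ndarray, ref: AmpliconReference) -> tuple[str, ...]:
    states = []
    for p in ref.cpg_positions:
        b = int(consensus[p])
        if b == _C:
            states.append("M")
        elif b == _T:
            states.append("U")
        else:
            states.append(".")
    return tuple(states)


def read_methylation(cpg_states: Sequence[str], min_cpgs: int = 20) -> tuple[float, int]:
    """Methylation percentage and bin index from per-CpG states.

    Raises ``ValueError`` when fewer than ``min_cpgs`` states are
    analyzable (M or U).
    """
    n_m = sum(s == "M" for s in cpg_states)
    n_a = sum(s in ("M", "U") for s in cpg_states)
    if n_a < min_cpgs:
        raise ValueError(f"only {n_a} analyzable CpGs (< {min_cpgs})")
    pct = 100.0 * n_m / n_a
    return pct, methylation_bin(pct)


@dataclass
class CallOptions:
    min_conversion: float = 0.95  # strict: rate must EXCEED this
    min_cpgs: int = 20
    min_non_cpg_c: int = 10
    identity_floor: float = 0.80
    min_read_length: int = 50
    major_allele: str | None = None  # default: reference major allele


def _finalize_call(read_id: str, cons: np.ndarray, ref: AmpliconReference, opts: CallOptions) -> ReadCall:
    reasons: list[str] = []
    rate = conversion_rate(cons, ref, opts.min_non_cpg_c)
    if rate is None:
        reasons.append("qc_insufficient")
    elif rate <= opts.min_conversion:
        reasons.append("low_conversion")
    allele = call_allele(cons, ref)
    major = opts.major_allele or ref.major_allele
    if int(cons[ref.variant_offset]) == 0:
        allele = "ambiguous"
        reasons.append("variant_uncovered")
    elif allele != major:
        reasons.append("minor_allele")
    states = cpg_states_from_consensus(cons, ref)
    n_a = sum(s in ("M", "U") for s in states)
    if n_a < opts.min_cpgs:
        reasons.append("cpg_missing")
    return ReadCall(
        read_id=read_id,
        allele=allele,
        conversion_rate=rate,
        cpg_states=states,
        pass_filters=not reasons,
        reasons=tuple(reasons),
    )


def call_read(read_id: str, seq: str, ref: AmpliconReference, opts: CallOptions | None = None) -> ReadCall:
    """Full per-read pipeline for a single-end read."""
    opts = opts or CallOptions()
    aln = align_to_amplicon(seq, ref, opts.identity_floor, opts.min_read_length)
    if aln is None:
        return ReadCall(read_id, "ambiguous", None, ("." ,) * N_CPGS, False, ("unmapped",))
    cons = _consensus_from_alignments([aln], ref.length)
    return _finalize_call(read_id, cons, ref, opts)


def call_read_pair(read_id: str, seq1: str, seq2: str, ref: AmpliconReference, opts: CallOptions | None = None) -> ReadCall:
    """Per-read pipeline for a mate pair (overlap consensus merge)."""
    opts = opts or CallOptions()
    alns = []
    for s in (seq1, seq2):
        aln = align_to_amplicon(s, ref, opts.identity_floor, opts.min_read_length)
        if aln is not None:
            alns.append(aln)
    if not alns:
        return ReadCall(read_id, "ambiguous", None, (".",) * N_CPGS, False, ("unmapped",))
    cons = _consensus_from_alignments(alns, ref.length)
    return _finalize_call(read_id, cons, ref, opts)


def call_reads(
    reads: Sequence[tuple[str, str]] | Sequence[tuple[str, str, str]],
    ref: AmpliconReference,
    opts: CallOptions | None = None,
) -> list[ReadCall]:
    """Vectorised calling for many reads.

    ``reads`` is a list of ``(read_id, seq)`` or ``(read_id, seq1, seq2)``
    tuples.  Alignment is batched over reads of equal length, which makes
    whole-sample processing fast; the per-read call semantics are identical
    to :func:`call_read` / :func:`call_read_pair`.
    """
    opts = opts or CallOptions()
    refenc = ref.encoded
    # collect every mate, remembering (read index, mate slot)
    mates: list[tuple[int, str]] = []
    for i, tup in enumerate(reads):
        for s in tup[1:]:
            mates.append((i, s))
    # batch by length
    aln_by_read: dict[int, list[Alignment]] = {i: [] for i in range(len(reads))}
    unmappable: set[int] = set()
    by_len: dict[int, list[int]] = {}
    for j, (i, s) in enumerate(mates):
        by_len.setdefault(len(s), []).append(j)
    for lr, idxs in by_len.items():
        if lr < opts.min_read_length or lr > ref.length:
            continue
        block = np.vstack([encode_seq(mates[j][1]) for j in idxs])
        offs, revs, idents = _align_batch(block, refenc, opts.identity_floor)
        for k, j in enumerate(idxs):
            i = mates[j][0]
            if offs[k] < 0:
                continue
            top = encode_seq(reverse_complement(mates[j][1])) if revs[k] else block[k]
            aln_by_read[i].append(Alignment(int(offs[k]), bool(revs[k]), float(idents[k]), np.asarray(top)))
    calls = []
    for i, tup in enumerate(reads):
        rid = tup[0]
        alns = aln_by_read[i]
        if not alns:
            calls.append(ReadCall(rid, "ambiguous", None, (".",) * N_CPGS, False, ("unmapped",)))
            continue
        cons = _consensus_from_alignments(alns, ref.length)
        calls.append(_finalize_call(rid, cons, ref, opts))
    return calls


# ------------------------------------------------------------------ profiles


def profile_sample(
    calls: Iterable[ReadCall],
    sample_id: str,
    min_depth: int = 1,
) -> MethylationProfile:
    """Aggregate read calls into the per-sample methylation profile.

    Mean methylation is the pooled CpG-call fraction (total methylated
    calls over total analyzable calls across retained reads); with complete
    25-CpG reads this equals the mean of per-read percentages.  Every input
    read lands either in the retained set or in exactly one rejection
    bucket (its first failing filter).
    """
    reasons: dict[str, int] = {}
    n_total = 0
    bins = np.zeros(10, dtype=float)
    meth_calls = 0
    analyzable_calls = 0
    retained = 0
    for call in calls:
        n_total += 1
        if not call.pass_filters:
            reason = call.reasons[0] if call.reasons else "unknown"
            reasons[reason] = reasons.get(reason, 0) + 1
            continue
        retained += 1
        bins[call.bin_index] += 1
        meth_calls += call.n_methylated
        analyzable_calls += call.n_analyzable
    if retained < min_depth or retained == 0:
        return MethylationProfile(
            sample_id=sample_id,
            n_reads_total=n_total,
            n_reads_retained=retained,
            rejection_reasons=reasons,
            bin_fractions=np.zeros(10),
            mean_methylation_pct=float("nan"),
            no_data=True,
        )
    return MethylationProfile(
        sample_id=sample_id,
        n_reads_total=n_total,
        n_reads_retained=retained,
        rejection_reasons=reasons,
        bin_fractions=bins / retained,
        mean_methylation_pct=100.0 * meth_calls / analyzable_calls,
        no_data=False,
    )


def calls_to_frame(calls: Iterable[ReadCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "read_id": c.read_id,
            "allele": c.allele,
            "conversion_rate": c.conversion_rate,
            "n_methylated": c.n_methylated,
            "n_analyzable": c.n_analyzable,
            "methylation_pct": c.methylation_pct if c.n_analyzable else np.nan,
            "bin": c.bin_index if c.n_analyzable else -1,
            "pass_filters": c.pass_filters,
            "reasons": ";".join(c.reasons),
        })
    return pd.DataFrame(rows)
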