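"""From paired-end amplicon reads to a filtered, annotated variant-count table.

Stages: trim the constant flanks (discarding pairs whose flanks mismatch the
reference too much), merge mates over their overlap resolving disagreements
by base quality, filter the consensus on length and quality, aggregate exact
sequences into counts, annotate each variant at the amino-acid level, and
apply the analysis filters (minimum input coverage, at most two amino-acid
substitutions, no mixed synonymous/nonsynonymous variants).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .design import AmpliconDesign, reverse_complement, translate

ANNOTATION_COLUMNS = ["nt_seq", "aa_seq", "var_class", "n_nt_subs", "n_aa_subs", "aa_subs"]


@dataclass
class ReadPair:
    fwd_seq: str
    fwd_qual: Sequence[int]
    rev_seq: str
    rev_qual: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError("sequence and quality lengths differ within a mate")


class Rejection(Exception):
    """A read pair failing a processing filter; .reason carries the label."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def _mismatch_fraction(observed: str, expected: str) -> float:
    return sum(a != b for a, b in zip(observed, expected)) / len(expected)


def trim_constant_regions(pair: ReadPair, design: AmpliconDesign) -> ReadPair:
    """Strip the constant flanks from both mates.

    The forward mate is expected to start with ``flank5``; the reverse mate
    (read from the opposite strand) starts with the reverse complement of
    ``flank3``. A pair is rejected when either flank mismatches its
    reference at more than ``max_flank_mismatch_rate`` of positions.
    """
    if not design.flank5 or not design.flank3:
        raise ValueError("design flanks must be non-empty")
    f5 = design.flank5.upper()
    f3rc = reverse_complement(design.flank3.upper())
    if len(pair.fwd_seq) < len(f5) or len(pair.rev_seq) < len(f3rc):
        raise Rejection("flank_mismatch")
    tol = design.max_flank_mismatch_rate
    if _mismatch_fraction(pair.fwd_seq[: len(f5)], f5) > tol:
        raise Rejection("flank_mismatch")
    if _mismatch_fraction(pair.rev_seq[: len(f3rc)], f3rc) > tol:
        raise Rejection("flank_mismatch")
    return ReadPair(
        fwd_seq=pair.fwd_seq[len(f5):],
        fwd_qual=list(pair.fwd_qual[len(f5):]),
        rev_seq=pair.rev_seq[len(f3rc):],
        rev_qual=list(pair.rev_qual[len(f3rc):]),
    )


def merge_read_pair(
    trimmed: ReadPair, min_overlap: int = 20, min_overlap_identity: float = 0.8
) -> tuple[str, list[int]]:
    """Merge trimmed mates into a single consensus over the variant region.

    The reverse mate is reverse-complemented onto the forward strand and the
    ungapped overlap offset maximising matches-minus-mismatches is chosen
    (ties favour the longest overlap). At overlap disagreements the base
    with the higher Phred score wins and keeps its quality; ties go to the
    forward mate. Pairs whose best candidate overlap is shorter than
    ``min_overlap`` or below ``min_overlap_identity`` are rejected.
    """
    fwd, fq = trimmed.fwd_seq, list(trimmed.fwd_qual)
    rev = reverse_complement(trimmed.rev_seq)
    rq = list(trimmed.rev_qual)[::-1]

    best_len, best_score, best_matches = 0, None, 0
    for ov in range(min(len(fwd), len(rev)), min_overlap - 1, -1):
        a, b = fwd[-ov:], rev[:ov]
        matches = sum(x == y for x, y in zip(a, b))
        score = 2 * matches - ov  # matches - mismatches
        if best_score is None or score > best_score:
            best_score, best_len, best_matches = score, ov, matches
    if best_score is None or best_matches / best_len < min_overlap_identity:
        raise Rejection("no_overlap")

    ov = best_len
    head_seq, head_q = fwd[:-ov], fq[:-ov]
    tail_seq, tail_q = rev[ov:], rq[ov:]
    mid_seq, mid_q = [], []
    for i in range(ov):
        bf, qf = fwd[len(fwd) - ov + i], fq[len(fwd) - ov + i]
        br, qr = rev[i], rq[i]
        if bf == br:
            mid_seq.append(bf)
            mid_q.append(max(qf, qr))
        elif qr > qf:
            mid_seq.append(br)
            mid_q.append(qr)
        else:
            mid_seq.append(bf)
            mid_q.append(qf)
    return head_seq + "".join(mid_seq) + tail_seq, head_q + mid_q + tail_q


def quality_length_filter(
    consensus_seq: str, consensus_qual: Sequence[int], design: AmpliconDesign
) -> tuple[bool, str | None]:
    """Accept a consensus iff it has the expected length and passes the Phred rule.

    N bases are treated as quality 0, so any N fails the default Q30 rule.
    """
    if len(consensus_seq) != design.expected_len:
        return False, "length"
    quals = [0 if b == "N" else q for b, q in zip(consensus_seq, consensus_qual)]
    stat = min(quals) if design.quality_rule == "min" else float(np.mean(quals))
    if stat < design.min_phred:
        return False, "quality"
    return True, None


def _levenshtein(a: str, b: str, limit: int) -> int:
    """Banded edit distance; returns limit+1 when the distance exceeds limit."""
    try:
        import edlib

        d = edlib.align(a, b, k=limit)["editDistance"]
        return d if d >= 0 else limit + 1
    except ImportError:  # pragma: no cover - edlib present in practice
        if a == b:
            return 0
        prev = list(range(len(b) + 1))
        for i, ca in enumerate(a, 1):
            cur = [i]
            for j, cb in enumerate(b, 1):
                cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
            if min(cur) > limit:
                return limit + 1
            prev = cur
        return prev[-1]


def aggregate_variants(
    sample_seqs: dict[str, Iterable[str]], correct_dist: int = 0
) -> pd.DataFrame:
    """Aggregate passing consensus sequences into a variant-by-sample count table.

    Rows are ordered lexicographically by nucleotide sequence. With
    ``correct_dist`` > 0 an abundance-greedy error-correction pass absorbs
    each less-abundant sequence into the most abundant unassigned sequence
    within that Levenshtein distance (off by default: exact deduplication).
    """
    counters = {sample: Counter(seqs) for sample, seqs in sample_seqs.items()}
    all_seqs = sorted(set().union(*(c.keys() for c in counters.values())) or set())
    table = pd.DataFrame(
        {sample: [c.get(s, 0) for s in all_seqs] for sample, c in counters.items()},
        index=pd.Index(all_seqs, name="nt_seq"),
        dtype=np.int64,
    )
    if correct_dist > 0 and len(table) > 1:
        totals = table.sum(axis=1)
        order = sorted(table.index, key=lambda s: (-totals[s], s))
        assigned: dict[str, str] = {}
        for center in order:
            if center in assigned:
                continue
            assigned[center] = center
            for other in order:
                if other in assigned:
                    continue
                if _levenshtein(center, other, correct_dist) <= correct_dist:
                    assigned[other] = center
        table = table.groupby(table.index.map(assigned)).sum()
        table.index.name = "nt_seq"
        table = table.sort_index()
    return table


def annotate_variant(nt_seq: str, design: AmpliconDesign) -> dict:
    """Annotate one variant against the WT coding sequence.

    Classifies as wildtype / synonymous / missense / nonsense, or
    ``rejected`` when a nonsynonymous variant also carries a synonymous
    change in a different codon (such variants confound the amino-acid-level
    analysis and are excluded). Positions are 1-based over the peptide.
    """
    wt = design.wt_coding_seq
    if len(nt_seq) != len(wt):
        raise ValueError(f"variant length {len(nt_seq)} != design length {len(wt)}")
    nt_seq = nt_seq.upper()
    n_nt_subs = sum(a != b for a, b in zip(nt_seq, wt))
    aa_seq = translate(nt_seq)
    wt_aa = design.wt_aa_seq

    aa_subs = []
    has_synonymous_codon = False
    for i in range(design.n_codons):
        codon_changed = nt_seq[3 * i: 3 * i + 3] != wt[3 * i: 3 * i + 3]
        if not codon_changed:
            continue
        if aa_seq[i] == wt_aa[i]:
            has_synonymous_codon = True
        else:
            aa_subs.append((i + 1, wt_aa[i], aa_seq[i]))
    n_aa_subs = len(aa_subs)

    if n_nt_subs == 0:
        var_class, reason = "wildtype", None
    elif n_aa_subs == 0:
        var_class, reason = "synonymous", None
    elif has_synonymous_codon:
        var_class, reason = "rejected", "mixed_synonymous"
    elif "*" in aa_seq:
        var_class, reason = "nonsense", None
    else:
        var_class, reason = "missense", None

    return {
        "nt_seq": nt_seq,
        "aa_seq": aa_seq,
        "var_class": var_class,
        "n_nt_subs": n_nt_subs,
        "n_aa_subs": n_aa_subs,
        "aa_subs": ";".join(f"{w}{p}{m}" for p, w, m in aa_subs),
        "reject_reason": reason,
    }


def parse_aa_subs(token: str) -> list[tuple[int, str, str]]:
    """Parse a semicolon-joined substitution string like 'A2V;F4L'."""
    subs = []
    for part in str(token).split(";"):
        part = part.strip()
        if not part:
            continue
        subs.append((int(part[1:-1]), part[0], part[-1]))
    return subs


def annotate_table(counts: pd.DataFrame, design: AmpliconDesign) -> pd.DataFrame:
    """Attach amino-acid annotations to an aggregated count table."""
    ann = pd.DataFrame([annotate_variant(s, design) for s in counts.index])
    out = pd.concat([ann.drop(columns=["reject_reason"]), counts.reset_index(drop=True)], axis=1)
    return out.sort_values("nt_seq", kind="mergesort").reset_index(drop=True)


def input_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("input")]


def output_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("output")]


def apply_variant_filters(
    table: pd.DataFrame, min_input_reads: int = 50, max_aa_subs: int = 2
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the analysis filters to an annotated count table.

    Retains variants with at least ``min_input_reads`` in every input
    replicate, at most ``max_aa_subs`` amino-acid substitutions, and a
    non-rejected class. Returns the filtered table and per-filter tallies.
    """
    if table.empty:
        raise ValueError("empty variant table")
    in_cols = input_columns(table)
    if not in_cols:
        raise ValueError("table has no input count columns")
    low_input = (table[in_cols] < min_input_reads).any(axis=1)
    too_many = table["n_aa_subs"] > max_aa_subs
    rejected = table["var_class"] == "rejected"
    keep = ~(low_input | too_many | rejected)
    tallies = {
        "low_input": int(low_input.sum()),
        "too_many_aa_subs": int(too_many.sum()),
        "rejected_class": int(rejected.sum()),
        "retained": int(keep.sum()),
    }
    return table[keep].reset_index(drop=True), tallies


# ---------------------------------------------------------------------------
# FASTQ-level driver


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(fastq1: str | Path, fastq2: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files."""
    with _open_text(fastq1) as f1, _open_text(fastq2) as f2:
        while True:
            block1 = [f1.readline() for _ in range(4)]
            block2 = [f2.readline() for _ in range(4)]
            if not block1[0] or not block2[0]:
                break
            yield ReadPair(
                fwd_seq=block1[1].strip().upper(),
                fwd_qual=[ord(c) - 33 for c in block1[3].strip()],
                rev_seq=block2[1].strip().upper(),
                rev_qual=[ord(c) - 33 for c in block2[3].strip()],
            )


def process_sample(
    fastq1: str | Path, fastq2: str | Path, design: AmpliconDesign
) -> tuple[list[str], Counter]:
    """Run trim/merge/filter over one sample; returns passing sequences and reject tallies."""
    passing: list[str] = []
    tallies: Counter = Counter()
    for pair in read_fastq_pairs(fastq1, fastq2):
        try:
            trimmed = trim_constant_regions(pair, design)
            seq, qual = merge_read_pair(trimmed, min_overlap=design.min_overlap)
        except Rejection as rej:
            tallies[rej.reason] += 1
            continue
        ok, reason = quality_length_filter(seq, qual, design)
        if not ok:
            tallies[reason] += 1
            continue
        passing.append(seq)
        tallies["pass"] += 1
    return passing, tallies


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV: sample_id, role (input|output), replicate, fastq1, fastq2."""
    sheet = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    required = {"sample_id", "role", "replicate", "fastq1", "fastq2"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if not set(sheet["role"]).issubset({"input", "output"}):
        raise ValueError("sample roles must be 'input' or 'output'")
    return sheet


def count_samples(
    sheet: pd.DataFrame, design: AmpliconDesign, correct_dist: int = 0
) -> tuple[pd.DataFrame, dict[str, Counter]]:
    """Process every sample in a sheet into one annotated count table.

    Count columns are named '<role><replicate>' (e.g. input1, output3).
    """
    sample_seqs: dict[str, list[str]] = {}
    stats: dict[str, Counter] = {}
    for row in sheet.itertuples(index=False):
        name = f"{row.role}{row.replicate}"
        seqs, tallies = process_sample(row.fastq1, row.fastq2, design)
        sample_seqs[name] = seqs
        stats[name] = tallies
    order = sorted(sample_seqs, key=lambda s: (s.startswith("output"), s))
    counts = aggregate_variants({k: sample_seqs[k] for k in order}, correct_dist=correct_dist)
    return annotate_table(counts, design), stats


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical tab-delimited count table.

    Deterministic layout: rows lexicographic by nt_seq; annotation columns
    first, then input columns, then output columns, each sorted by replicate.
    """
    cols = [c for c in ANNOTATION_COLUMNS if c in table.columns]
    cols += sorted(input_columns(table)) + sorted(output_columns(table))
    out = table[cols].sort_values("nt_seq", kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    table["aa_subs"] = table["aa_subs"].astype(str)
    return table
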