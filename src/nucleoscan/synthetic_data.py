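"""Synthetic DMS experiments with full ground truth.

Emulates the study design end to end: an error-prone-PCR library over a
126-nt coding sequence (configurable distribution of nucleotide
substitutions per molecule), growth selection that multiplies variant
frequencies by exp(true enrichment), replicate count noise with a Poisson
base plus multiplicative overdispersion (negative binomial) and an
additive variant-level log-noise component, and optional paired-end FASTQ
emission so the read-processing stage can be exercised end to end.

All randomness flows from a single numpy Generator; identical seeds give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import AmpliconDesign, reverse_complement
from .variant_calling import annotate_table

#: Fixed arbitrary 126-nt ORF used as the default synthetic wild type.
#: Deliberately NOT the real amyloid-beta coding sequence, so tests cannot
#: silently depend on real-data codon conventions.
SYNTHETIC_WT_CODING = (
    "ATGATAGAATTAAATGCGCCACTGCGGTGGGTTCTGCATATCAAGACAGATGAAATACCT"
    "AAAACGGCGCGGTACCAGCTAGCTTTTACTGCAGCAAGCATAAGACCGGTTCAATGGCAATTTCCA"
)

#: Library composition preset: fraction of molecules carrying k nucleotide
#: substitutions, mirroring an error-prone-PCR spectrum dominated by WT,
#: single- and double-nt molecules.
LIBRARY_SPECTRUM = {0: 0.299, 1: 0.238, 2: 0.218, 3: 0.151, 4: 0.094}

NUCLEOTIDES = np.array(list("ACGT"))


def synthetic_design(flank5: str = "ACGTACGTGGCCTAACTTACGCAGT",
                     flank3: str = "TGACCTTAGGCATCGATACCGTGCA") -> AmpliconDesign:
    """An AmpliconDesign over the synthetic wild type with 25-nt flanks."""
    return AmpliconDesign(wt_coding_seq=SYNTHETIC_WT_CODING, flank5=flank5, flank3=flank3)


# ---------------------------------------------------------------------------
# Library


def _mutate(wt: str, k: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(wt), size=k, replace=False)
    seq = list(wt)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(3)]
    return "".join(seq)


def simulate_library(
    wt_coding_seq: str,
    n_molecules: int = 100_000,
    mutation_spectrum: dict[int, float] | None = None,
    poisson_lambda: float | None = None,
    max_subs: int = 4,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Sample an error-prone-PCR library of molecules; aggregate to variants.

    Each molecule carries k nucleotide substitutions with k drawn from
    ``mutation_spectrum`` (a {k: probability} table, default
    :data:`LIBRARY_SPECTRUM`) or, if ``poisson_lambda`` is given, from a
    Poisson truncated at ``max_subs``. Substituted positions are uniform
    without replacement and the replacement base uniform over the three
    alternatives. Returns a frequency table (nt_seq, frequency) with the
    wild type always present.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    wt = wt_coding_seq.upper()
    if poisson_lambda is not None:
        ks = np.arange(max_subs + 1)
        from scipy.stats import poisson

        probs = poisson.pmf(ks, poisson_lambda)
        probs /= probs.sum()
        spectrum = dict(zip(ks.tolist(), probs.tolist()))
    else:
        spectrum = mutation_spectrum or LIBRARY_SPECTRUM
    ks = np.array(sorted(spectrum))
    probs = np.array([spectrum[k] for k in ks], float)
    probs /= probs.sum()
    draws = rng.choice(ks, size=n_molecules, p=probs)
    counts: dict[str, int] = {wt: 0}
    for k in draws:
        seq = wt if k == 0 else _mutate(wt, int(k), rng)
        counts[seq] = counts.get(seq, 0) + 1
    if counts[wt] == 0:
        counts[wt] = 1  # WT always present
    total = sum(counts.values())
    lib = pd.DataFrame(
        {"nt_seq": sorted(counts), "frequency": [counts[s] / total for s in sorted(counts)]}
    )
    return lib


def balanced_library(
    wt_coding_seq: str,
    n_variants: int = 2000,
    wt_fraction: float = 0.2,
    freq_log_sd: float = 0.5,
    max_nt_subs: int = 2,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """A library of distinct variants with log-normal frequency spread.

    Convenience generator for calibration studies: enumerates distinct
    variants (mix of 1- and 2-nt substitutions) and assigns them log-normal
    relative frequencies, with the wild type pinned at ``wt_fraction`` of
    the pool. The narrower frequency spread keeps per-variant coverage
    comparable across the library, so a target median input count can be
    set directly through the sequencing depth.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    wt = wt_coding_seq.upper()
    seqs = {wt}
    while len(seqs) < n_variants + 1:
        k = int(rng.integers(1, max_nt_subs + 1))
        seqs.add(_mutate(wt, k, rng))
    variants = sorted(seqs - {wt})
    raw = np.exp(rng.normal(0.0, freq_log_sd, size=len(variants)))
    freqs = (1.0 - wt_fraction) * raw / raw.sum()
    lib = pd.DataFrame(
        {"nt_seq": [wt] + variants, "frequency": np.concatenate([[wt_fraction], freqs])}
    )
    return lib.sort_values("nt_seq", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# True effects


@dataclass
class EffectModel:
    """Region-structured true enrichments for a modular mutational landscape.

    Single amino-acid substitutions draw their true enrichment from a
    normal distribution specific to the region of their position
    (aggregation-core-like C-terminal positions strongly negative,
    N-terminal positions near neutral, gatekeeper positions positive);
    nonsense variants get a large negative constant; doubles are additive
    with normal epistasis noise of standard deviation tau.
    """

    region_map: dict[int, str] = field(default_factory=dict)
    region_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"Nt": (0.0, 1.0), "Ct": (-3.0, 1.0), "gatekeeper": (1.0, 0.5)}
    )
    stop_effect: float = -4.0
    tau: float = 0.2

    def __post_init__(self) -> None:
        if not self.region_map:
            n = len(SYNTHETIC_WT_CODING) // 3
            self.region_map = default_region_map(n)
        for mean, sd in self.region_params.values():
            if sd < 0:
                raise ValueError("region sd must be >= 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


def default_region_map(n_positions: int) -> dict[int, str]:
    """First and last positions gatekeeper; first ~60% Nt; remainder Ct."""
    split = int(round(0.6 * n_positions))
    out = {}
    for pos in range(1, n_positions + 1):
        if pos in (1, n_positions):
            out[pos] = "gatekeeper"
        elif pos <= split:
            out[pos] = "Nt"
        else:
            out[pos] = "Ct"
    return out


def assign_true_effects(
    library: pd.DataFrame,
    design: AmpliconDesign,
    effect_model: EffectModel | None = None,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Attach true enrichments to a library; returns the truth table.

    One effect is drawn per distinct (position, mutant aa) substitution and
    reused across all variants carrying it; synonymous variants are neutral,
    nonsense variants get the stop effect, doubles are additive plus
    epistasis noise. NS_true = ES_true - ES_true(WT) = ES_true since WT is 0.
    """
    from .variant_calling import parse_aa_subs

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    model = effect_model or EffectModel(region_map=default_region_map(design.n_codons))
    counts_like = library.set_index("nt_seq")[[]]
    annotated = annotate_table(counts_like, design)
    annotated = annotated.merge(library, on="nt_seq", how="left")

    effect_cache: dict[tuple[int, str], float] = {}

    def single_effect(pos: int, mut: str) -> float:
        key = (pos, mut)
        if key not in effect_cache:
            mean, sd = model.region_params[model.region_map[pos]]
            effect_cache[key] = float(rng.normal(mean, sd))
        return effect_cache[key]

    es = np.zeros(len(annotated))
    for i, row in enumerate(annotated.itertuples(index=False)):
        if row.var_class in ("wildtype", "synonymous", "rejected"):
            continue
        if "*" in row.aa_seq:
            es[i] = model.stop_effect
            continue
        subs = parse_aa_subs(row.aa_subs)
        es[i] = sum(single_effect(p, m) for p, _w, m in subs)
        if len(subs) == 2 and model.tau > 0:
            es[i] += rng.normal(0.0, model.tau)
    annotated["es_true"] = es
    annotated["ns_true"] = es  # WT true enrichment is 0 by construction
    return annotated


# ---------------------------------------------------------------------------
# Selection and counts


@dataclass
class NoiseModel:
    """Per-replicate sequencing depths and noise parameters.

    ``m_in``/``m_out`` >= 1 inflate the count variance multiplicatively
    (negative binomial with variance m * mean; m = 1 is exactly Poisson);
    ``a`` is the variance of an additive variant-level log-normal noise on
    the selection step, independent per variant and replicate.
    """

    input_depth: tuple[float, ...] = (1e6, 1e6, 1e6)
    output_depth: tuple[float, ...] = (1e6, 1e6, 1e6)
    m_in: tuple[float, ...] = (1.0, 1.0, 1.0)
    m_out: tuple[float, ...] = (1.0, 1.0, 1.0)
    a: tuple[float, ...] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        n = len(self.input_depth)
        for name in ("output_depth", "m_in", "m_out", "a"):
            if len(getattr(self, name)) != n:
                raise ValueError("noise model fields must share the replicate count")
        if min(self.input_depth) <= 0 or min(self.output_depth) <= 0:
            raise ValueError("depths must be positive")
        if min(self.m_in) < 1 or min(self.m_out) < 1:
            raise ValueError("multiplicative modifiers must be >= 1")
        if min(self.a) < 0:
            raise ValueError("additive variance must be >= 0")

    @property
    def n_replicates(self) -> int:
        return len(self.input_depth)


def _overdispersed_counts(
    mean: np.ndarray, m: float, rng: np.random.Generator
) -> np.ndarray:
    """Counts with variance m * mean: Poisson at m=1, else negative binomial."""
    mean = np.asarray(mean, float)
    if m == 1.0:
        return rng.poisson(mean)
    # NB(r, p) with p = 1/m, r = mean/(m-1): var = mean * m
    r = np.where(mean > 0, mean / (m - 1.0), 1.0)
    out = np.where(mean > 0, rng.negative_binomial(r, 1.0 / m), 0)
    return out


def simulate_selection(
    truth: pd.DataFrame,
    noise: NoiseModel,
    rng: np.random.Generator | int = 0,
    wt_selection_noise: bool = False,
) -> pd.DataFrame:
    """Simulate replicate input/output counts from a truth table.

    Input counts are overdispersed around depth x frequency; the selection
    step multiplies frequencies by exp(es_true + eps) with eps ~
    Normal(0, sqrt(a)) per variant and replicate, renormalises, and draws
    output counts at the output depth. The wild type anchors the scores, so
    its selection noise is off by default (a per-replicate offset on every
    score would otherwise alias into the centering step).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    truth = truth.reset_index(drop=True)
    freq = truth["frequency"].to_numpy(float)
    freq = freq / freq.sum()
    es = truth["es_true"].to_numpy(float)
    wt_mask = truth["n_nt_subs"].to_numpy() == 0

    table = truth.drop(columns=["frequency", "es_true", "ns_true"]).copy()
    for r in range(noise.n_replicates):
        cin = _overdispersed_counts(noise.input_depth[r] * freq, noise.m_in[r], rng)
        eps = rng.normal(0.0, np.sqrt(noise.a[r]), size=len(freq)) if noise.a[r] > 0 else np.zeros(len(freq))
        if not wt_selection_noise:
            eps[wt_mask] = 0.0
        w = freq * np.exp(es + eps)
        w = w / w.sum()
        cout = _overdispersed_counts(noise.output_depth[r] * w, noise.m_out[r], rng)
        table[f"input{r + 1}"] = cin.astype(np.int64)
        table[f"output{r + 1}"] = cout.astype(np.int64)
    in_cols = [f"input{r + 1}" for r in range(noise.n_replicates)]
    out_cols = [f"output{r + 1}" for r in range(noise.n_replicates)]
    ann_cols = [c for c in table.columns if c not in in_cols + out_cols]
    return table[ann_cols + in_cols + out_cols]


# ---------------------------------------------------------------------------
# FASTQ emission


def emit_fastq(
    counts: pd.DataFrame,
    design: AmpliconDesign,
    out_dir: str | Path,
    read_len: int = 125,
    base_error_rate: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Write paired FASTQ files regenerating every counted molecule.

    For each sample column and each variant, emits `count` read pairs:
    forward read = 5' flank + variant region (truncated at ``read_len``),
    reverse read = reverse complement from the 3' end. Phred qualities are
    constant and consistent with ``base_error_rate`` (Q40 when 0), and
    substitution sequencing errors are applied per base at that rate.
    Returns a sample sheet DataFrame pointing at the written files.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    amplicon_len = len(design.flank5) + design.expected_len + len(design.flank3)
    if read_len <= max(len(design.flank5), len(design.flank3)):
        raise ValueError("read_len does not reach past the constant flanks")
    if 2 * read_len < amplicon_len + design.min_overlap:
        raise ValueError("read_len too short for the required mate overlap")
    if base_error_rate > 0:
        phred = max(2, int(round(-10 * np.log10(base_error_rate))))
    else:
        phred = 40
    qchar = chr(phred + 33)

    sample_cols = [c for c in counts.columns if c.startswith(("input", "output"))]
    sheet_rows = []
    for sample in sample_cols:
        f1 = out_dir / f"{sample}_1.fastq"
        f2 = out_dir / f"{sample}_2.fastq"
        with open(f1, "w") as fh1, open(f2, "w") as fh2:
            serial = 0
            for nt_seq, n in zip(counts["nt_seq"], counts[sample]):
                amplicon = design.flank5 + nt_seq + design.flank3
                fwd = amplicon[:read_len]
                rev = reverse_complement(amplicon)[:read_len]
                for _ in range(int(n)):
                    serial += 1
                    fwd_out, rev_out = fwd, rev
                    if base_error_rate > 0:
                        fwd_out = _seq_errors(fwd, base_error_rate, rng)
                        rev_out = _seq_errors(rev, base_error_rate, rng)
                    rid = f"@{sample}.{serial}"
                    fh1.write(f"{rid}\n{fwd_out}\n+\n{qchar * len(fwd_out)}\n")
                    fh2.write(f"{rid}\n{rev_out}\n+\n{qchar * len(rev_out)}\n")
        role = "input" if sample.startswith("input") else "output"
        sheet_rows.append(
            {
                "sample_id": sample,
                "role": role,
                "replicate": int(sample[len(role):]),
                "fastq1": str(f1),
                "fastq2": str(f2),
            }
        )
    return pd.DataFrame(sheet_rows)


def _seq_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    flips = rng.random(len(seq)) < rate
    if not flips.any():
        return seq
    chars = list(seq)
    for i in np.flatnonzero(flips):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# One-call experiment


def simulate_experiment(
    design: AmpliconDesign | None = None,
    n_variants: int = 2000,
    median_input_count: float = 500.0,
    effect_model: EffectModel | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a complete synthetic experiment: (count table, truth table).

    Uses the balanced library so the sequencing depth can be set to hit the
    requested median per-variant input count with three replicates.
    """
    rng = np.random.default_rng(seed)
    design = design or synthetic_design()
    lib = balanced_library(design.wt_coding_seq, n_variants=n_variants, rng=rng)
    truth = assign_true_effects(lib, design, effect_model, rng=rng)
    freq = truth["frequency"].to_numpy(float)
    non_wt = truth["n_nt_subs"].to_numpy() > 0
    depth = median_input_count / np.median(freq[non_wt])
    if noise is None:
        noise = NoiseModel(
            input_depth=(depth,) * 3, output_depth=(depth,) * 3,
        )
    counts = simulate_selection(truth, noise, rng=rng)
    return counts, truth
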