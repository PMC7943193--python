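"""Sequence-feature analyses: property changes, weighted correlation, charge.

Variant effects are related to physicochemistry via difference scores
(mutant minus wild-type property value, summed over substitutions),
correlated with nucleation scores using an error-weighted Pearson
coefficient, and summarised by the peptide's charge composition: the
number of positively ({R,K}) and negatively ({D,E}) charged residues and
their difference, the net charge. Histidine is treated as polar-uncharged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .variant_calling import parse_aa_subs

POSITIVE_AA = set("RK")
NEGATIVE_AA = set("DE")
#: Residue classes eligible for the charge analysis: polar, charged, and glycine.
POLAR_CHARGED_GLY = set("STNQYCH") | {"G"} | POSITIVE_AA | NEGATIVE_AA

#: Kyte-Doolittle hydropathy index (hydrophobicity; positive = hydrophobic).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def read_aaindex(path: str | Path, ids: list[str] | None = None) -> dict[str, dict[str, float]]:
    """Parse AAindex1 flat-file records into {accession: {aa: value}}.

    Each record starts with an ``H`` accession line; the ``I`` line is
    followed by two rows of ten values in the order
    A/R/N/D/C/Q/E/G/H/I and L/K/M/F/P/S/T/W/Y/V.
    """
    order = "ARNDCQEGHILKMFPSTWYV"
    out: dict[str, dict[str, float]] = {}
    text = Path(path).read_text()
    for record in text.split("//"):
        m = re.search(r"^H\s+(\S+)", record, re.MULTILINE)
        i = re.search(r"^I\s.*?\n(.*?)(?=^\S|\Z)", record, re.MULTILINE | re.DOTALL)
        if not m or not i:
            continue
        acc = m.group(1)
        if ids is not None and acc not in ids:
            continue
        values = [float("nan") if v in ("NA", "-") else float(v) for v in i.group(1).split()]
        if len(values) != 20:
            raise ValueError(f"AAindex record {acc}: expected 20 values, got {len(values)}")
        out[acc] = dict(zip(order, values))
    if ids is not None:
        missing = set(ids) - set(out)
        if missing:
            raise KeyError(f"AAindex ids not found: {sorted(missing)}")
    return out


def property_delta(aa_subs: str | list[tuple[int, str, str]], prop: dict[str, float]) -> float:
    """Difference score: sum over substitutions of p(mutant) - p(wild-type).

    Synonymous variants score 0; substitutions to a stop raise, since stop
    codons carry no property value.
    """
    subs = parse_aa_subs(aa_subs) if isinstance(aa_subs, str) else aa_subs
    total = 0.0
    for _pos, wt, mut in subs:
        if mut == "*" or wt == "*":
            raise ValueError("stop_variant: property deltas undefined for stop codons")
        total += prop[mut] - prop[wt]
    return total


def weighted_pearson(
    x: np.ndarray, y: np.ndarray, sigmas: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Error-weighted Pearson correlation.

    Weights default to 1/sigma^2. Returns (r, p, n_eff) where the p-value
    uses a t approximation at the effective sample size
    ``n_eff = (sum w)^2 / sum(w^2)`` (Kish), documented rather than exact.
    Invariant to rescaling all weights by a positive constant.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if weights is None:
        if sigmas is None:
            weights = np.ones_like(x)
        else:
            weights = 1.0 / np.asarray(sigmas, float) ** 2
    w = np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    if vx == 0 or vy == 0:
        raise ValueError("zero variance in x or y")
    r = float(cov / np.sqrt(vx * vy))
    n_eff = float(w.sum() ** 2 / (w ** 2).sum())
    if n_eff <= 2 or abs(r) >= 1.0:
        p = 0.0 if abs(r) >= 1.0 else 1.0
    else:
        t = r * np.sqrt((n_eff - 2) / (1.0 - r ** 2))
        p = float(2.0 * stats.t.sf(abs(t), df=n_eff - 2))
    return r, p, n_eff


@dataclass
class ChargeProfile:
    n_positive: int
    n_negative: int
    eligible: bool

    @property
    def net_charge(self) -> int:
        return self.n_positive - self.n_negative

    @property
    def n_charged(self) -> int:
        return self.n_positive + self.n_negative


def charge_profile(aa_seq: str, aa_subs: str | list[tuple[int, str, str]] = "") -> ChargeProfile:
    """Charge composition of the full mutant sequence.

    ``eligible`` is True only when every substitution stays within the
    polar/charged/glycine residue classes (both wild-type and mutant side),
    so the charge analysis is not confounded by hydrophobicity changes.
    """
    n_pos = sum(aa in POSITIVE_AA for aa in aa_seq)
    n_neg = sum(aa in NEGATIVE_AA for aa in aa_seq)
    subs = parse_aa_subs(aa_subs) if isinstance(aa_subs, str) else aa_subs
    eligible = all(
        wt in POLAR_CHARGED_GLY and mut in POLAR_CHARGED_GLY for _p, wt, mut in subs
    )
    return ChargeProfile(n_positive=n_pos, n_negative=n_neg, eligible=eligible)


def charge_group_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """NS distributions grouped by (net_charge, n_charged).

    Considers eligible single and double amino-acid missense variants (all
    substitutions within the polar/charged/glycine classes) plus synonymous
    variants, which carry the wild-type profile. Reports per-group size,
    median, and quartiles.
    """
    rows = []
    eligible_classes = {"missense", "synonymous", "wildtype"}
    for row in scores.itertuples(index=False):
        if row.var_class not in eligible_classes or row.n_aa_subs > 2:
            continue
        prof = charge_profile(row.aa_seq, row.aa_subs)
        if not prof.eligible:
            continue
        rows.append(
            {
                "net_charge": prof.net_charge,
                "n_charged": prof.n_charged,
                "ns": row.ns,
                "n_aa_subs": row.n_aa_subs,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["net_charge", "n_charged", "n", "median", "q25", "q75"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["net_charge", "n_charged"])["ns"]
        .agg(n="size", median="median", q25=lambda s: s.quantile(0.25), q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return out.sort_values(["net_charge", "n_charged"]).reset_index(drop=True)


def feature_table(
    scores: pd.DataFrame, properties: dict[str, dict[str, float]]
) -> pd.DataFrame:
    """Per-variant difference scores and charge fields for non-stop variants."""
    rows = []
    for row in scores.itertuples(index=False):
        if row.var_class not in {"missense", "synonymous", "wildtype"}:
            continue
        rec = {"nt_seq": row.nt_seq, "aa_subs": row.aa_subs, "ns": row.ns, "sigma": row.sigma}
        for pid, prop in properties.items():
            rec[f"delta_{pid}"] = property_delta(row.aa_subs, prop)
        prof = charge_profile(row.aa_seq, row.aa_subs)
        rec.update(
            n_positive=prof.n_positive,
            n_negative=prof.n_negative,
            net_charge=prof.net_charge,
            n_charged=prof.n_charged,
            charge_eligible=prof.eligible,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def correlate_features(features: pd.DataFrame, feature_cols: list[str]) -> pd.DataFrame:
    """Weighted Pearson of NS against each requested feature column."""
    rows = []
    for col in feature_cols:
        sub = features.dropna(subset=[col, "ns", "sigma"])
        r, p, n_eff = weighted_pearson(sub[col], sub["ns"], sigmas=sub["sigma"])
        rows.append({"feature": col, "r_weighted": r, "p": p, "n": len(sub), "n_eff": n_eff})
    return pd.DataFrame(rows)
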