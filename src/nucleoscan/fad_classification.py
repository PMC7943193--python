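"""Discrimination of disease-labeled variants and score-based categorisation.

Given a label file of amino-acid substitutions known to cause dominant
familial Alzheimer's disease (fAD), the ROC analysis asks how well the
nucleation score separates those positives from every other scored single
amino-acid missense variant. All scored singles are then placed into
mutually exclusive categories: known fAD, candidate fAD (significant
increase), protective-like (significant decrease), or benign (WT-like).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .variant_calling import parse_aa_subs

LABELS = ("dominant_fAD", "recessive_fAD", "unknown")


def read_label_set(path: str | Path) -> pd.DataFrame:
    """Read a label TSV with columns substitution (e.g. 'E22G'), label, source."""
    labels = pd.read_csv(path, sep="\t", comment="#")
    if not {"substitution", "label"}.issubset(labels.columns):
        raise ValueError("label file needs 'substitution' and 'label' columns")
    bad = set(labels["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    for sub in labels["substitution"]:
        parse_aa_subs(sub)  # validates format
    return labels


def packaged_fad_labels() -> pd.DataFrame:
    """The editable fAD label fixture shipped with the package."""
    with resources.as_file(
        resources.files("nucleoscan.data").joinpath("fad_labels.tsv")
    ) as path:
        return read_label_set(path)


def _single_missense(scores: pd.DataFrame) -> pd.DataFrame:
    return scores[(scores["var_class"] == "missense") & (scores["n_aa_subs"] == 1)]


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    missing_positives: list[str]


def roc_auc(scores: pd.DataFrame, labels: pd.DataFrame) -> ROCResult:
    """ROC of NS for dominant-fAD singles versus all other scored singles.

    The AUC is the normalised Mann-Whitney U statistic (average ranks, so
    ties count one half); the curve sweeps the NS threshold. Labeled
    positives absent from the score table are reported, not silently
    dropped from the label set.
    """
    singles = _single_missense(scores)
    positives = set(labels.loc[labels["label"] == "dominant_fAD", "substitution"])
    if not positives:
        raise ValueError("label set contains no dominant_fAD substitutions")
    is_pos = singles["aa_subs"].isin(positives).to_numpy()
    found = set(singles.loc[is_pos, "aa_subs"])
    missing = sorted(positives - found)
    y = is_pos.astype(int)
    x = singles["ns"].to_numpy(float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    ranks = rankdata(x)  # average ranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    fpr, tpr, thr = roc_curve(y, x)
    return ROCResult(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, n_pos=n_pos, n_neg=n_neg,
        missing_positives=missing,
    )


def categorize_variants(scores: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Mutually exclusive categories over scored single-aa missense variants.

    Precedence: a labeled dominant-fAD substitution is ``known_fAD``
    whatever its effect class; the rest follow their class — increase ->
    ``candidate_fAD``, decrease -> ``protective_like``, wt_like -> ``benign``.
    """
    singles = _single_missense(scores).copy()
    positives = set(labels.loc[labels["label"] == "dominant_fAD", "substitution"])
    mapping = {"increase": "candidate_fAD", "decrease": "protective_like", "wt_like": "benign"}
    category = singles["effect_class"].map(mapping)
    category[singles["aa_subs"].isin(positives)] = "known_fAD"
    singles["category"] = category
    return singles


def category_counts(categorized: pd.DataFrame) -> dict[str, int]:
    counts = categorized["category"].value_counts().to_dict()
    return {
        k: int(counts.get(k, 0))
        for k in ("known_fAD", "candidate_fAD", "benign", "protective_like")
    }
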