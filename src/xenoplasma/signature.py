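"""Tumor gene-signature scoring and therapy-response classification.

The intersection of differentially abundant genes across comparisons defines
a tumor-specific signature (by default the 8 genes PHF14, PELP1, RPL7L1,
HPRT1, RELN, RNU1-75P, RNU5A-8P, RNVU1-19). A sample's signature score is the
mean CPM of the signature genes; a one-feature logistic model on the score,
fitted on a stratified training split, classifies tumor-bearing versus
successfully treated samples and is summarized by ROC/AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

__all__ = [
    "DEFAULT_SIGNATURE",
    "dag_overlap",
    "signature_score",
    "SignatureModel",
    "train_logistic",
    "roc_auc",
]

DEFAULT_SIGNATURE = (
    "PHF14",
    "PELP1",
    "RPL7L1",
    "HPRT1",
    "RELN",
    "RNU1-75P",
    "RNU5A-8P",
    "RNVU1-19",
)

#: |coefficient| beyond which a one-feature logistic fit (on standardized
#: scores) is flagged as perfectly separated
SEPARATION_CAP = 30.0


def dag_overlap(named_sets: dict[str, set]) -> pd.DataFrame:
    """Counts of every intersection region of 2–4 gene sets (Venn partition).

    Returns one row per non-empty membership combination with columns
    ``members`` (frozenset of set names exclusively covering the region) and
    ``count``; region counts sum to the size of the union.
    """
    k = len(named_sets)
    if not 2 <= k <= 4:
        raise ValueError("dag_overlap supports 2 to 4 sets")
    names = list(named_sets)
    rows = []
    for r in range(1, k + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(named_sets[c]) for c in combo))
            outside = set.union(
                *(set(named_sets[c]) for c in names if c not in combo), set()
            )
            rows.append(
                {"members": frozenset(combo), "count": len(inside - outside)}
            )
    return pd.DataFrame(rows)


def signature_score(
    cpm: pd.DataFrame, gene_list=DEFAULT_SIGNATURE, log2: bool = False
) -> pd.Series:
    """Per-sample mean expression of the signature genes (CPM scale).

    Genes absent from the matrix are imputed as 0 with a warning — plausible
    in shallow plasma samples. With ``log2=True`` the mean is taken over
    log2(CPM+1) values instead.
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("empty gene list")
    present = [g for g in gene_list if g in cpm.index]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    missing = sorted(set(gene_list) - set(present))
    if missing:
        warnings.warn(
            f"{len(missing)} signature genes absent, imputed 0: {missing}",
            stacklevel=2,
        )
    block = cpm.reindex(gene_list).fillna(0.0)
    if log2:
        block = np.log2(block + 1.0)
    return block.mean(axis=0).rename("signature_score")


@dataclass
class SignatureModel:
    """One-feature logistic classifier over a signature score."""

    genes: tuple
    intercept: float
    coefficient: float
    training_samples: tuple
    decision_threshold: float = 0.5
    perfectly_separated: bool = False
    score_mean: float = 0.0
    score_scale: float = 1.0
    _clf: LogisticRegression = field(default=None, repr=False)

    def predict_proba(self, scores: pd.Series) -> pd.Series:
        z = (scores.to_numpy(dtype=float) - self.score_mean) / self.score_scale
        logit = self.intercept + self.coefficient * z
        return pd.Series(1.0 / (1.0 + np.exp(-logit)), index=scores.index, name="p_positive")


def train_logistic(
    scores: pd.Series,
    labels: pd.Series,
    split_fraction: float = 0.7,
    seed: int = 0,
    genes=DEFAULT_SIGNATURE,
) -> tuple[SignatureModel, pd.DataFrame]:
    """Fit a logistic classifier on a stratified train split of the scores.

    Returns the model and a table of held-out samples with predicted
    probabilities and true labels. Perfect separation is not an error: the
    coefficient is capped and flagged. Deterministic under ``seed``.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    idx = scores.index.to_numpy()
    train_idx, test_idx = train_test_split(
        idx, train_size=split_fraction, random_state=seed, stratify=y
    )
    y_train = labels.loc[train_idx].astype(int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split lost one class; adjust split_fraction")
    mu = float(scores.loc[train_idx].mean())
    sd = float(scores.loc[train_idx].std()) or 1.0
    X_train = ((scores.loc[train_idx] - mu) / sd).to_numpy().reshape(-1, 1)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    clf.fit(X_train, y_train)
    coef = float(clf.coef_[0, 0])
    intercept = float(clf.intercept_[0])
    # a single score separates perfectly iff the class ranges do not overlap
    s0 = scores.loc[train_idx][y_train.to_numpy() == 0]
    s1 = scores.loc[train_idx][y_train.to_numpy() == 1]
    separated = bool(s0.max() < s1.min() or s1.max() < s0.min())
    if abs(coef) > SEPARATION_CAP:
        coef = float(np.clip(coef, -SEPARATION_CAP, SEPARATION_CAP))
    model = SignatureModel(
        genes=tuple(genes),
        intercept=intercept,
        coefficient=coef,
        training_samples=tuple(train_idx),
        perfectly_separated=separated,
        score_mean=mu,
        score_scale=sd,
        _clf=clf,
    )
    held_out = pd.DataFrame(
        {
            "score": scores.loc[test_idx],
            "label": labels.loc[test_idx].astype(int),
            "p_positive": model.predict_proba(scores.loc[test_idx]),
        }
    )
    return model, held_out


def roc_auc(predicted_scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC via the Mann–Whitney U statistic (ties count ½).

    AUC = U / (n_pos · n_neg) where U is computed from average ranks of the
    positive-class scores — exactly the probability a random positive outranks
    a random negative, with ties counted one half.
    """
    s = np.asarray(predicted_scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))

    # ROC polyline over decreasing thresholds
    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    ss = s[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    distinct = np.nonzero(np.diff(ss))[0]
    keep = np.r_[distinct, len(ss) - 1]
    roc = pd.DataFrame(
        {
            "threshold": ss[keep],
            "fpr": fps[keep] / n_neg,
            "tpr": tps[keep] / n_pos,
        }
    )
    roc = pd.concat(
        [pd.DataFrame({"threshold": [np.inf], "fpr": [0.0], "tpr": [0.0]}), roc],
        ignore_index=True,
    )
    return roc, auc
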