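"""Coding-potential scoring: ORF features + Fickett TESTCODE + hexamer bias.

The scorer mirrors the CPAT design: four features of the spliced transcript
sequence — longest-ORF length, ORF coverage, the Fickett (1982) TESTCODE
statistic, and the mean in-frame hexamer log-likelihood ratio — combined by a
logistic regression trained on coding/noncoding example sequences.  The
decision boundary defaults to probability 0.345, the threshold commonly used
with CPAT; it can be recalibrated (Youden's J) on validation data since that
constant was tuned for CPAT's original training corpus, not ours.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

from .orf import find_max_orf

__all__ = [
    "fickett_score",
    "HexamerTable",
    "build_hexamer_table",
    "hexamer_llr",
    "CodingModel",
    "fit_coding_model",
    "coding_probability",
    "CodingPotentialScore",
    "sequence_features",
]

# ---------------------------------------------------------------------------
# Fickett TESTCODE lookup tables (Fickett, NAR 1982), embedded as constants.
# Position parameter: asymmetry of each base across the three codon positions;
# content parameter: overall base composition.  Probabilities are read off the
# published tables by thresholding, then combined with the published weights.
# ---------------------------------------------------------------------------

_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)

_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)


def _lookup(value: float, paras: tuple, probs: tuple) -> float:
    for idx, threshold in enumerate(paras):
        if value >= threshold:
            return probs[idx]
    return probs[-1]


def fickett_score(seq: str) -> float:
    """TESTCODE value of ``seq`` (case-insensitive; N bases are not counted).

    Requires >= 200 nt, consistent with the minimum-length filter upstream of
    the coding-potential stage.
    """
    seq = seq.upper()
    if len(seq) < 200:
        raise ValueError(f"fickett_score requires >= 200 nt, got {len(seq)}")
    total = sum(seq.count(b) for b in "ACGT")
    score = 0.0
    for base in "ACGT":
        counts = [seq[i::3].count(base) for i in range(3)]
        position_value = max(counts) / (min(counts) + 1.0)
        score += (
            _lookup(position_value, _POSITION_PARA, _POSITION_PROB[base])
            * _POSITION_WEIGHT[base]
        )
        content_value = seq.count(base) / total if total else 0.0
        score += (
            _lookup(content_value, _CONTENT_PARA, _CONTENT_PROB[base])
            * _CONTENT_WEIGHT[base]
        )
    return score


# ---------------------------------------------------------------------------
# Hexamer usage bias
# ---------------------------------------------------------------------------

_HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
_HEXAMER_INDEX = {h: i for i, h in enumerate(_HEXAMERS)}


@dataclass
class HexamerTable:
    """Smoothed hexamer frequencies for the coding and noncoding classes."""

    coding_freq: np.ndarray
    noncoding_freq: np.ndarray
    pseudocount: float
    n_coding: int
    n_noncoding: int

    def __post_init__(self) -> None:
        for arr in (self.coding_freq, self.noncoding_freq):
            if arr.shape != (4096,):
                raise ValueError("hexamer frequency arrays must have length 4096")
            if not np.all(arr > 0):
                raise ValueError("all smoothed hexamer frequencies must be > 0")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError("hexamer frequencies must sum to 1")
        self.log_ratio = np.log(self.coding_freq / self.noncoding_freq)

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.round(self.coding_freq, 12).tobytes())
        h.update(np.round(self.noncoding_freq, 12).tobytes())
        return h.hexdigest()[:16]

    def swapped(self) -> "HexamerTable":
        return HexamerTable(self.noncoding_freq.copy(), self.coding_freq.copy(),
                            self.pseudocount, self.n_noncoding, self.n_coding)

    def to_dict(self) -> dict:
        return {
            "coding_freq": self.coding_freq.tolist(),
            "noncoding_freq": self.noncoding_freq.tolist(),
            "pseudocount": self.pseudocount,
            "n_coding": self.n_coding,
            "n_noncoding": self.n_noncoding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HexamerTable":
        return cls(np.asarray(d["coding_freq"]), np.asarray(d["noncoding_freq"]),
                   d["pseudocount"], d["n_coding"], d["n_noncoding"])


def _count_hexamers(seq: str, step: int, counts: np.ndarray) -> None:
    seq = seq.upper()
    for i in range(0, len(seq) - 5, step):
        idx = _HEXAMER_INDEX.get(seq[i : i + 6])
        if idx is not None:  # hexamers containing N are skipped
            counts[idx] += 1


def build_hexamer_table(coding_seqs, noncoding_seqs, pseudocount: float = 1.0) -> HexamerTable:
    """In-frame hexamer counts of coding ORF sequences (frame 0, step 3) vs
    all-frame hexamers of noncoding sequences, Laplace-smoothed and normalized."""
    coding_seqs = list(coding_seqs)
    noncoding_seqs = list(noncoding_seqs)
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("both sequence classes must be non-empty")
    if len(coding_seqs) < 10 or len(noncoding_seqs) < 10:
        raise ValueError("need >= 10 sequences per class to estimate hexamer usage")
    c = np.zeros(4096)
    n = np.zeros(4096)
    for s in coding_seqs:
        _count_hexamers(s, 3, c)
    for s in noncoding_seqs:
        _count_hexamers(s, 1, n)
    c = (c + pseudocount) / (c.sum() + pseudocount * 4096)
    n = (n + pseudocount) / (n.sum() + pseudocount * 4096)
    return HexamerTable(c, n, pseudocount, len(coding_seqs), len(noncoding_seqs))


def hexamer_llr(seq: str, table: HexamerTable) -> float:
    """Mean log(f_coding/f_noncoding) over in-frame hexamers of the longest ORF
    (whole sequence, frame 0, when no complete ORF exists)."""
    seq = seq.upper()
    if len(seq) < 6:
        raise ValueError("sequence shorter than one hexamer")
    aa, start, _frame = find_max_orf(seq)
    region = seq[start : start + 3 * aa] if aa > 0 else seq
    vals = []
    for i in range(0, len(region) - 5, 3):
        idx = _HEXAMER_INDEX.get(region[i : i + 6])
        if idx is not None:
            vals.append(table.log_ratio[idx])
    return float(np.mean(vals)) if vals else 0.0


# ---------------------------------------------------------------------------
# Feature extraction and the logistic model
# ---------------------------------------------------------------------------

FEATURE_NAMES = ("max_orf_nt", "orf_coverage", "fickett", "hexamer_llr")


def sequence_features(seq: str, table: HexamerTable) -> tuple[float, float, float, float]:
    """(max_orf_nt, orf_coverage, fickett, hexamer_llr) of one sequence."""
    aa, _start, _frame = find_max_orf(seq)
    orf_nt = 3 * aa
    return (
        float(orf_nt),
        orf_nt / len(seq),
        fickett_score(seq),
        hexamer_llr(seq, table),
    )


@dataclass
class CodingModel:
    """Fitted logistic coding/noncoding classifier over standardized features."""

    coef: np.ndarray
    intercept: float
    means: np.ndarray
    scales: np.ndarray
    threshold: float = 0.345
    table_checksum: str = ""
    holdout_auc: float = float("nan")
    feature_names: tuple = FEATURE_NAMES

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        x = (np.atleast_2d(features) - self.means) / self.scales
        z = x @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "coef": self.coef.tolist(),
                "intercept": self.intercept,
                "means": self.means.tolist(),
                "scales": self.scales.tolist(),
                "threshold": self.threshold,
                "table_checksum": self.table_checksum,
                "holdout_auc": self.holdout_auc,
                "feature_names": list(self.feature_names),
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CodingModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["coef"]), d["intercept"], np.asarray(d["means"]),
                   np.asarray(d["scales"]), d["threshold"], d["table_checksum"],
                   d["holdout_auc"], tuple(d["feature_names"]))


def fit_coding_model(features: np.ndarray, labels: np.ndarray, seed: int,
                     threshold: float = 0.345, recalibrate: bool = False,
                     test_size: float = 0.3,
                     table: HexamerTable | None = None) -> CodingModel:
    """Fit the logistic classifier; ``labels`` 1 = coding, 0 = noncoding.

    Features are standardized; a held-out split (deterministic in ``seed``)
    reports the AUC.  With ``recalibrate`` the decision threshold is moved to
    the Youden-optimal point on the held-out set instead of the 0.345 default.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both coding and noncoding examples")
    if counts.min() < 50:
        raise ValueError("need >= 50 examples per class")
    means = features.mean(axis=0)
    scales = features.std(axis=0)
    scales[scales == 0] = 1.0
    x = (features - means) / scales
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, labels, test_size=test_size, random_state=seed, stratify=labels
    )
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(x_tr, y_tr)
    prob_te = clf.predict_proba(x_te)[:, 1]
    auc = float(roc_auc_score(y_te, prob_te))
    if recalibrate:
        fpr, tpr, thr = roc_curve(y_te, prob_te)
        threshold = float(thr[np.argmax(tpr - fpr)])
    return CodingModel(
        coef=clf.coef_[0].copy(), intercept=float(clf.intercept_[0]),
        means=means, scales=scales, threshold=threshold,
        table_checksum=table.checksum() if table is not None else "",
        holdout_auc=auc,
    )


@dataclass
class CodingPotentialScore:
    """Per-transcript coding-potential features and combined probability."""

    max_orf_nt: int
    orf_coverage: float
    fickett: float
    hexamer_llr: float
    coding_probability: float
    external_scores: dict = field(default_factory=dict)

    @property
    def is_coding(self) -> bool:
        raise AttributeError("use coding_call(threshold) — the call depends on the model threshold")

    def coding_call(self, threshold: float) -> bool:
        internal = self.coding_probability > threshold
        external = any(v > 0 for v in self.external_scores.values())
        return internal or external


@dataclass
class TranscriptScorer:
    """A trained model + hexamer table bundled for cascade use."""

    model: CodingModel
    table: HexamerTable

    def score(self, seq: str, external_scores: dict | None = None) -> "CodingPotentialScore":
        return coding_probability(seq, self.model, self.table, external_scores)


def coding_probability(seq: str, model: CodingModel, table: HexamerTable,
                       external_scores: dict | None = None) -> CodingPotentialScore:
    """Score one spliced transcript sequence with a trained model."""
    if model is None:
        raise ValueError("untrained model")
    feats = sequence_features(seq, table)
    prob = float(model.predict_proba(np.asarray(feats))[0])
    if not math.isfinite(prob):
        prob = 0.0
    return CodingPotentialScore(
        max_orf_nt=int(feats[0]), orf_coverage=feats[1], fickett=feats[2],
        hexamer_llr=feats[3], coding_probability=min(max(prob, 0.0), 1.0),
        external_scores=dict(external_scores or {}),
    )
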