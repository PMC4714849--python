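"""Expression containers, JS tissue-specificity, and sex-bias statistics.

The tissue-specificity score of a transcript is ``max_t 1 - sqrt(JSD(p, e_t))``
where ``p`` is its expression profile normalized across tissues, ``e_t`` the
point-mass profile of tissue ``t`` and JSD the Jensen-Shannon divergence in
bits; it is 1 exactly when the transcript is expressed in a single tissue and
approaches 0 for ubiquitous expression.

Sex bias per tissue is tested on raw counts with a two-sided exact binomial
test under library-size-proportional sampling (the same null as DEGseq's
random-sampling model, computed exactly), with BH FDR across transcripts per
tissue; a transcript is sex-biased when |log2FC| > 1 and q < 0.05.  At the
locus level, a multi-isoform locus is sex-biased when more than 75% of its
isoforms are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "SpecificityResult",
    "js_specificity",
    "js_specificity_profile",
    "classify_tissue_specific",
    "sex_bias_test",
    "sex_bias_table",
    "bh_fdr",
    "locus_sex_bias_ratio",
    "SexBiasResult",
]


@dataclass
class ExpressionMatrix:
    """Transcripts x samples abundances plus per-sample metadata.

    ``samples`` must carry columns ``tissue``, ``sex`` (F/M/mixed) and, for the
    counts kind, ``library_size``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    kind: str = "fpkm"  # or "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("fpkm", "counts"):
            raise ValueError(f"unknown expression kind {self.kind!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if self.kind == "counts" and "library_size" not in self.samples.columns:
            raise ValueError("counts matrices require a library_size column")

    def tissue_means(self) -> pd.DataFrame:
        """Transcripts x tissues table (mean across the samples of each tissue)."""
        tissues = self.samples.loc[list(self.values.columns), "tissue"]
        return self.values.T.groupby(tissues.to_numpy()).mean().T

    @classmethod
    def read(cls, values_path, samples_path, kind: str = "fpkm") -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(values, samples, kind)

    def write(self, values_path, samples_path=None) -> None:
        self.values.to_csv(values_path, sep="\t")
        if samples_path is not None:
            self.samples.to_csv(samples_path, sep="\t")


@dataclass
class SpecificityResult:
    transcript_id: str
    scores: dict = field(default_factory=dict)  # tissue -> 1 - sqrt(JSD)
    js_score: float = float("nan")
    tissue: str | None = None
    valid: bool = True


def _entropy_bits(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=-1)


def js_specificity_profile(profile, tissues=None) -> SpecificityResult:
    """Specificity of a single per-tissue expression vector."""
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 2:
        raise ValueError("profile must be a vector over >= 2 tissues")
    if (profile < 0).any():
        raise ValueError("negative expression values")
    tissues = list(tissues) if tissues is not None else [f"t{i}" for i in range(profile.size)]
    total = profile.sum()
    if total == 0:
        return SpecificityResult("", {t: float("nan") for t in tissues}, valid=False)
    p = profile / total
    hp = _entropy_bits(p)
    scores = {}
    for k, tissue in enumerate(tissues):
        m = p.copy() / 2.0
        m[k] += 0.5
        jsd = _entropy_bits(m) - hp / 2.0  # H(e_t) = 0
        jsd = min(max(jsd, 0.0), 1.0)
        scores[tissue] = 1.0 - np.sqrt(jsd)
    best = max(scores, key=lambda t: (scores[t], t))
    return SpecificityResult("", scores, js_score=scores[best], tissue=best)


def js_specificity(expr: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-transcript JS specificity over tissues.

    Accepts an ExpressionMatrix (tissue means are taken) or a transcripts x
    tissues DataFrame.  All-zero profiles are flagged invalid (NaN score).
    """
    means = expr.tissue_means() if isinstance(expr, ExpressionMatrix) else expr
    tissues = list(means.columns)
    rows = []
    for tid, profile in means.iterrows():
        r = js_specificity_profile(profile.to_numpy(), tissues)
        rows.append({"transcript_id": tid, "js_score": r.js_score if r.valid else np.nan,
                     "tissue": r.tissue, "valid": r.valid,
                     **{f"score_{t}": r.scores[t] for t in tissues}})
    return pd.DataFrame(rows).set_index("transcript_id")


def classify_tissue_specific(results: pd.DataFrame, cutoff: float = 0.25,
                             strict: bool = True) -> pd.Series:
    """Boolean per transcript; by default specific iff js_score strictly > cutoff."""
    js = results["js_score"]
    return js > cutoff if strict else js >= cutoff


def sex_bias_test(x_f: int, x_m: int, n_f: float, n_m: float) -> tuple[float, float]:
    """(log2FC female over male, exact two-sided binomial p).

    log2FC uses a 0.5 pseudocount on library-size-normalized counts; the test
    treats the x_f+x_m reads as draws with null success probability
    N_f/(N_f+N_m).
    """
    if n_f <= 0 or n_m <= 0:
        raise ValueError("library sizes must be positive")
    if x_f < 0 or x_m < 0:
        raise ValueError("negative counts")
    log2fc = float(np.log2(((x_f + 0.5) / n_f) / ((x_m + 0.5) / n_m)))
    total = x_f + x_m
    if total == 0:
        return log2fc, 1.0
    p0 = n_f / (n_f + n_m)
    p = binomtest(int(x_f), int(total), p0, alternative="two-sided").pvalue
    return log2fc, float(p)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, clipped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def sex_bias_table(counts: ExpressionMatrix, lfc_threshold: float = 1.0,
                   q_threshold: float = 0.05) -> pd.DataFrame:
    """Per-(transcript, tissue) sex-bias calls from a counts ExpressionMatrix.

    Requires one female and one male sample (or pooled columns) per tissue.
    FDR correction is applied per tissue across transcripts.
    """
    if counts.kind != "counts":
        raise ValueError("sex-bias testing requires raw counts")
    meta = counts.samples
    frames = []
    for tissue, group in meta.groupby("tissue"):
        f = group.index[group["sex"] == "F"]
        m = group.index[group["sex"] == "M"]
        if len(f) == 0 or len(m) == 0:
            continue
        x_f = counts.values[f].sum(axis=1).to_numpy()
        x_m = counts.values[m].sum(axis=1).to_numpy()
        n_f = float(meta.loc[f, "library_size"].sum())
        n_m = float(meta.loc[m, "library_size"].sum())
        res = [sex_bias_test(int(a), int(b), n_f, n_m) for a, b in zip(x_f, x_m)]
        lfc = np.array([r[0] for r in res])
        pv = np.array([r[1] for r in res])
        qv = bh_fdr(pv)
        call = np.where(
            (np.abs(lfc) > lfc_threshold) & (qv < q_threshold),
            np.where(lfc > 0, "female_biased", "male_biased"),
            "unbiased",
        )
        frames.append(pd.DataFrame({
            "transcript_id": counts.values.index, "tissue": tissue,
            "log2fc": lfc, "p": pv, "q": qv, "call": call,
        }))
    if not frames:
        raise ValueError("no tissue with both female and male samples")
    return pd.concat(frames, ignore_index=True)


@dataclass
class SexBiasResult:
    locus_id: str
    ratio: float
    biased: bool
    n_isoforms: int
    n_biased: int


def locus_sex_bias_ratio(isoform_calls: dict[str, list[bool]],
                         ratio_threshold: float = 0.75) -> list[SexBiasResult]:
    """Roll isoform-level calls up to loci.

    ``isoform_calls`` maps locus id -> per-isoform biased flags (an isoform
    counts as biased if called biased in any tissue).  Multi-isoform loci are
    biased iff ratio strictly > 0.75; single-isoform loci inherit the call.
    """
    out = []
    for locus, calls in isoform_calls.items():
        if not calls:
            raise ValueError(f"locus {locus!r} has no isoforms")
        n_biased = sum(bool(c) for c in calls)
        ratio = n_biased / len(calls)
        if len(calls) == 1:
            biased = bool(calls[0])
        else:
            biased = ratio > ratio_threshold
        out.append(SexBiasResult(locus, ratio, biased, len(calls), n_biased))
    return out
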