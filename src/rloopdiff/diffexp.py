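"""Negative-binomial differential testing for binned DRIP-Seq and RNA-Seq counts.

The model is a per-feature two-group negative binomial with median-of-ratios
library-size normalization, method-of-moments dispersion, and a Wald test on
the log rate ratio:

    K_ij ~ NB(mean = s_j * q_g(j), variance = mu + alpha_i * mu^2)

with group rates estimated by the ratio estimator
``q_g = sum_j K_ij / sum_j s_j`` and standard errors from the Fisher
information ``I_g = sum_j mu_gj / (1 + alpha_i * mu_gj)``. No fold-change
shrinkage, outlier handling, or independent filtering is applied: numeric
parity with full GLM engines is not a goal, threshold/direction behaviour is.

The public surface follows the statsmodels convention: build a
:class:`NegativeBinomialDiff` model from a :class:`CountMatrix`, call
:meth:`~NegativeBinomialDiff.fit` for a contrast, and read estimates,
p-values and calls off the returned :class:`NBDiffResults`.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "CallParams",
    "DifferentialCalls",
    "NegativeBinomialDiff",
    "NBDiffResults",
    "estimate_size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "call_differential",
]

ALPHA_MIN = 1e-8


class CountMatrix:
    """Nonnegative integer feature x sample counts with a sample -> group design."""

    def __init__(self, counts: pd.DataFrame, design: Mapping[str, str]):
        if (counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")
        missing = [s for s in counts.columns if s not in design]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.counts = counts.astype(np.int64)
        self.design = pd.Series({s: design[s] for s in counts.columns}, name="group")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_in(self, group: str) -> list[str]:
        return list(self.design.index[self.design == group])

    def subset_features(self, feature_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[feature_ids], dict(self.design))

    def subset_groups(self, *groups: str) -> "CountMatrix":
        keep = [s for s in self.sample_ids if self.design[s] in groups]
        return CountMatrix(self.counts[keep], dict(self.design))


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-feature geometric mean over the features with
    all-positive counts; a sample's factor is the median of its count/reference
    ratios across those features.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("cannot normalize: no feature with all-positive counts")
    logs = np.log(mat[positive])
    log_geo_mean = logs.mean(axis=1)
    # median on the ratio scale (matters when the reference set has even size)
    factors = np.median(np.exp(logs - log_geo_mean[:, None]), axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design: Mapping[str, str],
    groups: tuple[str, str] | None = None,
    alpha_min: float = ALPHA_MIN,
) -> pd.Series:
    """Method-of-moments NB dispersion per feature.

    Normalized counts are pooled within groups: with grand within-group mean
    ``mu`` and pooled within-group variance ``v`` (df = n_samples - n_groups),
    ``alpha = max(alpha_min, (v - mu) / mu^2)``.
    """
    design = pd.Series(dict(design))
    samples = [s for s in counts.columns if groups is None or design[s] in groups]
    labels = design[samples]
    norm = counts[samples].to_numpy(dtype=float) / size_factors[samples].to_numpy()
    ss = np.zeros(len(counts))
    df = 0
    for g in labels.unique():
        cols = np.asarray(labels == g)
        n_g = int(cols.sum())
        if n_g < 2:
            continue
        sub = norm[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += n_g - 1
    if df == 0:
        raise ValueError("need >= 2 samples in some group to estimate dispersion")
    v = ss / df
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu > 0, (v - mu) / np.square(mu), 0.0)
    alpha = np.maximum(alpha, alpha_min)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def nb_wald_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    design: Mapping[str, str],
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Wald test of group B over group A; returns a table without q-values.

    Group rates use the ratio estimator ``q_g = sum K / sum s`` (pseudocount
    0.5 added to a zero numerator); the log-rate-difference standard error
    comes from the NB Fisher information under each group's fitted means.
    """
    group_a, group_b = contrast
    design = pd.Series(dict(design))
    cols: dict[str, list[str]] = {}
    for g in contrast:
        cols[g] = [s for s in counts.columns if design.get(s) == g]
        if len(cols[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    alpha = dispersions.loc[counts.index].to_numpy(dtype=float)

    def group_stats(g: str) -> tuple[np.ndarray, np.ndarray]:
        k = counts[cols[g]].to_numpy(dtype=float)
        s = size_factors[cols[g]].to_numpy(dtype=float)
        total = k.sum(axis=1)
        total = np.where(total == 0, 0.5, total)
        q = total / s.sum()
        mu = q[:, None] * s[None, :]
        info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
        return q, info

    q_a, info_a = group_stats(group_a)
    q_b, info_b = group_stats(group_b)
    log2fc = (np.log(q_b) - np.log(q_a)) / np.log(2.0)
    se_ln = np.sqrt(1.0 / info_a + 1.0 / info_b)
    z = (np.log(q_b) - np.log(q_a)) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(z))
    all_cols = cols[group_a] + cols[group_b]
    norm = counts[all_cols].to_numpy(dtype=float) / size_factors[all_cols].to_numpy()
    return pd.DataFrame(
        {
            "mean_normalized": norm.mean(axis=1),
            "log2fc": log2fc,
            "se_log2fc": se_ln / np.log(2.0),
            "p": p,
        },
        index=counts.index,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class CallParams:
    """Thresholds for calling differential features.

    DRIP bin contrasts use an FDR cut with a log2FC floor (1.0 for the
    genotype baseline, 1.5 for treatment contrasts); expression contrasts use
    a raw-p cut with no fold-change floor. All inequalities are strict.
    """

    fdr_max: float = 0.05
    lfc_min: float = 1.0
    p_max: float | None = None

    def __post_init__(self) -> None:
        if self.fdr_max <= 0 or (self.p_max is not None and self.p_max <= 0):
            raise ValueError("thresholds must be > 0")


@dataclass(frozen=True)
class DifferentialCalls:
    up: frozenset[str]
    down: frozenset[str]
    params: CallParams
    contrast: str = ""

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down call sets must be disjoint")

    @property
    def all_calls(self) -> frozenset[str]:
        return self.up | self.down


def call_differential(
    table: pd.DataFrame, params: CallParams, contrast: str = ""
) -> DifferentialCalls:
    """Threshold a differential table into up/down call sets.

    FDR mode: ``q < fdr_max`` and ``|log2fc| > lfc_min``. Raw-p mode
    (``params.p_max`` set): ``p < p_max`` with direction by sign of log2fc.
    """
    if params.p_max is not None:
        sig = table["p"] < params.p_max
        lfc_min = 0.0
    else:
        sig = table["q"] < params.fdr_max
        lfc_min = params.lfc_min
    up = frozenset(table.index[sig & (table["log2fc"] > lfc_min)])
    down = frozenset(table.index[sig & (table["log2fc"] < -lfc_min)])
    return DifferentialCalls(up=up, down=down, params=params, contrast=contrast)


class NegativeBinomialDiff:
    """Two-group NB differential model over a :class:`CountMatrix`.

    Size factors and dispersions are estimated from the samples of the two
    contrast groups only, so an unrelated condition cannot perturb a contrast.
    """

    def __init__(self, data: CountMatrix):
        self.data = data

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, design: Mapping[str, str]
    ) -> "NegativeBinomialDiff":
        return cls(CountMatrix(counts, design))

    def fit(
        self,
        contrast: tuple[str, str],
        alpha_min: float = ALPHA_MIN,
    ) -> "NBDiffResults":
        """Test group ``contrast[1]`` over ``contrast[0]``.

        BH adjustment is applied within the tested (already filtered) feature
        set of this contrast only.
        """
        sub = self.data.subset_groups(*contrast)
        counts = sub.counts
        size_factors = estimate_size_factors(counts)
        dispersions = estimate_dispersions(
            counts, size_factors, dict(sub.design), groups=contrast, alpha_min=alpha_min
        )
        table = nb_wald_test(counts, size_factors, dispersions, dict(sub.design), contrast)
        table["q"] = bh_adjust(table["p"].to_numpy())
        return NBDiffResults(
            model=self,
            contrast=contrast,
            table=table,
            size_factors=size_factors,
            dispersions=dispersions,
        )


@dataclass
class NBDiffResults:
    """Fitted per-feature estimates for one contrast.

    ``table`` columns: mean_normalized, log2fc (B over A), se_log2fc, p, q.
    """

    model: NegativeBinomialDiff
    contrast: tuple[str, str]
    table: pd.DataFrame
    size_factors: pd.Series
    dispersions: pd.Series
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def contrast_label(self) -> str:
        return f"{self.contrast[1]}_vs_{self.contrast[0]}"

    def calls(self, params: CallParams | None = None) -> DifferentialCalls:
        params = params or CallParams()
        return call_differential(self.table, params, contrast=self.contrast_label)

    def summary(self, params: CallParams | None = None) -> str:
        params = params or CallParams()
        calls = self.calls(params)
        mode = (
            f"p < {params.p_max}"
            if params.p_max is not None
            else f"FDR < {params.fdr_max}, |log2FC| > {params.lfc_min}"
        )
        lines = [
            "Negative-binomial Wald differential test",
            f"  contrast:        {self.contrast[1]} vs {self.contrast[0]}",
            f"  features tested: {len(self.table)}",
            f"  median dispersion: {float(self.dispersions.median()):.4g}",
            f"  call thresholds: {mode}",
            f"  up (accumulated/upregulated):   {len(calls.up)}",
            f"  down (depleted/downregulated):  {len(calls.down)}",
        ]
        return "\n".join(lines)

    def plot_ma(self, params: CallParams | None = None, ax=None):
        """MA-style scatter of log2FC against mean normalized signal."""
        import matplotlib.pyplot as plt

        params = params or CallParams()
        calls = self.calls(params)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        t = self.table
        colors = np.where(
            t.index.isin(calls.up), "crimson",
            np.where(t.index.isin(calls.down), "steelblue", "0.7"),
        )
        ax.scatter(np.log10(t["mean_normalized"] + 1), t["log2fc"], s=4, c=colors)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("log10 mean normalized count + 1")
        ax.set_ylabel(f"log2FC ({self.contrast[1]} / {self.contrast[0]})")
        ax.set_title(self.contrast_label)
        return ax

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature_id")
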