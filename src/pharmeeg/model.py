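"""Correlation-matrix PCA, Gaussian naive Bayes and MPS scoring.

The effect matrix (records x 132 post/pre ratios) is standardised
column-wise with the training mean and SD, and the symmetric
eigendecomposition of the resulting correlation matrix yields loadings
and eigenvalues; the first k = 6 component scores summarise each
record.  A Gaussian naive Bayes classifier models each training class
by independent per-component normal densities; test records receive a
posterior probability over the training classes, and each test group is
reported by the median posterior per class - the median probability of
similarity (MPS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import FitError, InputError, SchemaError
from .io import META_COLUMNS

_SD_FLOOR = 1e-12  # columns with smaller SD are treated as constant


def _split_meta(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    feat_cols = [c for c in df.columns if c not in META_COLUMNS]
    return df[meta_cols], df[feat_cols]


@dataclass
class PcaModel:
    """Correlation-matrix PCA fitted on training effect vectors."""

    feature_names: list[str]  # retained (non-constant) features, in order
    mean: np.ndarray  # training means of retained features
    sd: np.ndarray  # training SDs (ddof=1) of retained features
    loadings: np.ndarray  # retained features x k, orthonormal columns
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    evr: np.ndarray  # explained-variance fractions, all components
    k: int
    dropped_features: list[str] = field(default_factory=list)

    @property
    def pc_names(self) -> list[str]:
        return [f"PC{j + 1}" for j in range(self.k)]


def pca_fit(
    effects: pd.DataFrame,
    k: int = 6,
    *,
    variance_target: float | None = None,
) -> PcaModel:
    """Fit correlation-matrix PCA on an effect matrix.

    Columns are standardised by their training mean and SD; near-constant
    columns are dropped (and recorded on the model).  Components are
    sorted by eigenvalue and their sign fixed so that each component's
    largest-magnitude loading is positive, making score tables
    reproducible across runs and platforms.
    """
    _, X = _split_meta(effects)
    values = X.to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise InputError("effect matrix contains non-finite values")
    n, p = values.shape
    if n < k + 1:
        raise FitError(f"need at least k+1={k + 1} records to retain {k} components, got {n}")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    keep = sd > _SD_FLOOR
    dropped = [c for c, ok in zip(X.columns, keep) if not ok]
    names = [c for c, ok in zip(X.columns, keep) if ok]
    z = (values[:, keep] - mean[keep]) / sd[keep]
    corr = (z.T @ z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):  # deterministic sign convention
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    total = evals.sum()
    evr = evals / total if total > 0 else np.zeros_like(evals)
    k = min(k, len(evals))
    if variance_target is not None:
        k = int(np.searchsorted(np.cumsum(evr), variance_target) + 1)
        k = min(k, len(evals))
    return PcaModel(
        feature_names=names,
        mean=mean[keep],
        sd=sd[keep],
        loadings=evecs[:, :k],
        eigenvalues=evals,
        evr=evr,
        k=k,
        dropped_features=dropped,
    )


def pca_project(model: PcaModel, effects: pd.DataFrame) -> pd.DataFrame:
    """Project effect vectors onto the model's first k components.

    Metadata columns present in ``effects`` are carried through; the
    result has columns ``record_id``/``animal_id``/``group`` + ``PC1..PCk``.
    """
    meta, X = _split_meta(effects)
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise SchemaError(f"effect matrix lacks feature(s) required by the PCA model: {missing[:5]}")
    values = X[model.feature_names].to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise InputError("effect matrix contains non-finite values")
    z = (values - model.mean) / model.sd
    scores = z @ model.loadings
    out = meta.reset_index(drop=True).copy()
    for j, name in enumerate(model.pc_names):
        out[name] = scores[:, j]
    return out


def loadings_frame(model: PcaModel) -> pd.DataFrame:
    """Loadings as a features x components table (heatmap-ready)."""
    return pd.DataFrame(model.loadings, index=model.feature_names, columns=model.pc_names)


# ---------------------------------------------------------------------------
# Gaussian naive Bayes on PC scores


@dataclass
class NbcModel:
    """Per-class independent Gaussian densities over the PC scores."""

    classes: list[str]
    pc_names: list[str]
    means: pd.DataFrame  # classes x PCs
    variances: pd.DataFrame  # classes x PCs, floored
    priors: pd.Series  # per class, sums to 1
    variance_floor: float = 1e-9


def _pc_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("PC") and c[2:].isdigit()]
    if not cols:
        raise SchemaError(f"no PC columns found in {list(df.columns)}")
    return sorted(cols, key=lambda c: int(c[2:]))


def nbc_fit(
    scores: pd.DataFrame,
    *,
    class_col: str = "group",
    priors: Literal["uniform", "empirical"] = "uniform",
    variance_floor: float = 1e-9,
) -> NbcModel:
    """Fit per-class means and unbiased variances of the PC scores.

    Priors are uniform by default (reference groups are near-equally
    sized by design); empirical priors are available.  Zero within-class
    variances are floored to keep densities finite.
    """
    if class_col not in scores.columns:
        raise SchemaError(f"score table lacks the class column {class_col!r}")
    pc_cols = _pc_columns(scores)
    values = scores[pc_cols].to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise InputError("score table contains non-finite values")
    grouped = scores.groupby(class_col, sort=True)
    counts = grouped.size()
    singletons = counts[counts < 2]
    if not singletons.empty:
        raise FitError(
            f"class {singletons.index[0]!r} has {int(singletons.iloc[0])} record(s); "
            "at least 2 are required"
        )
    means = grouped[pc_cols].mean()
    variances = grouped[pc_cols].var(ddof=1).clip(lower=variance_floor)
    classes = list(means.index)
    if priors == "uniform":
        pr = pd.Series(1.0 / len(classes), index=classes)
    elif priors == "empirical":
        pr = counts / counts.sum()
    else:
        raise SchemaError(f"unknown priors mode {priors!r}")
    return NbcModel(
        classes=classes,
        pc_names=pc_cols,
        means=means,
        variances=variances,
        priors=pr,
        variance_floor=variance_floor,
    )


def nbc_posterior(model: NbcModel, scores: pd.DataFrame) -> pd.DataFrame:
    """Posterior class probabilities for each record (rows sum to 1).

    Densities are accumulated in the log domain and normalised with
    log-sum-exp, so extreme scores underflow gracefully.
    """
    pc_cols = _pc_columns(scores)
    if pc_cols != model.pc_names:
        raise SchemaError(
            f"score table PCs {pc_cols} do not match the fitted model's {model.pc_names}"
        )
    x = scores[pc_cols].to_numpy(float)  # n x k
    if not np.all(np.isfinite(x)):
        raise InputError("score table contains non-finite values")
    mu = model.means.to_numpy(float)  # C x k
    var = model.variances.to_numpy(float)
    log_prior = np.log(model.priors.to_numpy(float))
    # n x C log joint
    diff = x[:, None, :] - mu[None, :, :]
    log_lik = -0.5 * (diff**2 / var[None, :, :] + np.log(2.0 * np.pi * var[None, :, :])).sum(axis=2)
    log_joint = log_lik + log_prior[None, :]
    log_post = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
    post = np.exp(log_post)
    meta_cols = [c for c in META_COLUMNS if c in scores.columns]
    out = scores[meta_cols].reset_index(drop=True).copy()
    for ci, cls in enumerate(model.classes):
        out[cls] = post[:, ci]
    return out


# ---------------------------------------------------------------------------
# group-level reporting


@dataclass
class MpsTable:
    """Median probability of similarity per test group and training class."""

    table: pd.DataFrame  # groups x classes, entries in [0, 1]
    ranking: pd.DataFrame  # group, top_class, mps, tied


def mps_table(
    posteriors: pd.DataFrame,
    *,
    group_col: str = "group",
    classes: Sequence[str] | None = None,
) -> MpsTable:
    """Aggregate record posteriors into group medians and rank the top class.

    The median of an even number of records is the mean of the two middle
    values.  Ties in the top-class ranking are broken by class name order
    and flagged.
    """
    if group_col not in posteriors.columns:
        raise SchemaError(f"posterior table lacks the group column {group_col!r}")
    if posteriors.empty:
        raise InputError("posterior table is empty")
    if posteriors[group_col].isna().any() or (posteriors[group_col] == "").any():
        raise InputError("every record needs a non-empty group label")
    class_cols = list(classes) if classes is not None else [
        c for c in posteriors.columns if c not in META_COLUMNS
    ]
    table = posteriors.groupby(group_col, sort=True)[class_cols].median()
    rows = []
    for group, row in table.iterrows():
        best = row.max()
        winners = sorted(row.index[row == best])
        rows.append(
            dict(group=group, top_class=winners[0], mps=float(best), tied=len(winners) > 1)
        )
    return MpsTable(table=table, ranking=pd.DataFrame(rows))


@dataclass
class ClassificationResult:
    """All artefacts of one end-to-end classification run."""

    pca: PcaModel
    nbc: NbcModel
    train_scores: pd.DataFrame
    test_scores: pd.DataFrame
    posteriors: pd.DataFrame
    mps: MpsTable


def classify_group(
    train_effects: pd.DataFrame,
    test_effects: pd.DataFrame,
    *,
    k: int = 6,
    pca_population: Literal["training", "all"] = "training",
    priors: Literal["uniform", "empirical"] = "uniform",
    variance_floor: float = 1e-9,
    class_col: str = "group",
) -> ClassificationResult:
    """Full chain: PCA fit -> project both sets -> NBC fit -> posteriors -> MPS.

    ``pca_population="training"`` (default) fits the PCA on training
    records only, avoiding leakage of test records into the reduction;
    ``"all"`` pools both sets before fitting, mirroring workflows that
    compute component scores on every record at once.
    """
    if pca_population == "all":
        pooled = pd.concat([train_effects, test_effects], ignore_index=True)
        pca = pca_fit(pooled, k=k)
    elif pca_population == "training":
        pca = pca_fit(train_effects, k=k)
    else:
        raise SchemaError(f"unknown pca_population {pca_population!r}")
    train_scores = pca_project(pca, train_effects)
    test_scores = pca_project(pca, test_effects)
    nbc = nbc_fit(train_scores, class_col=class_col, priors=priors, variance_floor=variance_floor)
    posteriors = nbc_posterior(nbc, test_scores)
    mps = mps_table(posteriors, group_col=class_col)
    return ClassificationResult(
        pca=pca,
        nbc=nbc,
        train_scores=train_scores,
        test_scores=test_scores,
        posteriors=posteriors,
        mps=mps,
    )


def leave_one_out_mps(
    effects: pd.DataFrame,
    *,
    k: int = 6,
    priors: Literal["uniform", "empirical"] = "uniform",
    variance_floor: float = 1e-9,
    class_col: str = "group",
) -> tuple[float, MpsTable, pd.DataFrame]:
    """Leave-one-record-out class recovery on a labelled effect matrix.

    Each record's posterior is computed from models fitted without it;
    the per-group medians of those held-out posteriors form an MPS table
    whose top class is compared with the true group.  Returns
    ``(fraction of groups recovered, MPS table, per-record posteriors)``.
    """
    if class_col not in effects.columns:
        raise SchemaError(f"effect matrix lacks the class column {class_col!r}")
    rows = []
    for i in range(len(effects)):
        train = effects.drop(effects.index[i])
        held = effects.iloc[[i]]
        pca = pca_fit(train, k=k)
        nbc = nbc_fit(
            pca_project(pca, train), class_col=class_col, priors=priors,
            variance_floor=variance_floor,
        )
        post = nbc_posterior(nbc, pca_project(pca, held))
        rows.append(post.iloc[0])
    posteriors = pd.DataFrame(rows).reset_index(drop=True)
    mps = mps_table(posteriors, group_col=class_col)
    hits = (mps.ranking["top_class"] == mps.ranking["group"]).sum()
    return hits / len(mps.ranking), mps, posteriors
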