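"""Small-dataset best-subset MLR workflow with full validation.

The modelling protocol mirrors standard small-dataset QSPR practice:
descriptors are standardized (zero mean, unit sample sd), inter-correlated
descriptors (pairwise R² above a threshold) are filtered out, the data are
split into training and test sets by the deterministic Kennard–Stone max-min
procedure, and every k-descriptor subset is fitted by ordinary least squares
and ranked by the trimmed mean absolute error on the test set.  Model quality
is reported through internal (adjusted R², leave-one-out Q², MAE95 train) and
external (Q²_F1, Q²_F2, MAE95 test) metrics, and the applicability domain is
characterized by a Williams-type leverage/standardized-residual analysis.

The published six-descriptor solubility model for edaravone in (aqueous)
ethaline/glyceline is available from :func:`published_edaravone_model`; it
operates on externally standardized descriptors.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from eutsol.exceptions import DomainError, FitError, ValidationError
from eutsol.sigma import DescriptorTable

__all__ = [
    "MLRModel",
    "ValidationReport",
    "ADReport",
    "SplitPlan",
    "standardize",
    "correlation_filter",
    "kennard_stone",
    "fit_mlr",
    "predict",
    "published_edaravone_model",
    "mae95",
    "validate",
    "exhaustive_search",
    "applicability_domain",
    "size_scan",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, DescriptorTable):
        return X.frame
    if isinstance(X, pd.DataFrame):
        return X
    raise ValidationError("expected a DescriptorTable or DataFrame")


@dataclass(frozen=True)
class MLRModel:
    """Selected descriptor subset with OLS coefficients on standardized inputs.

    ``standardization`` maps each descriptor to the (mean, sd) applied at fit
    time, or is ``None`` when standardization happened externally (as for the
    published literature model).
    """

    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    standardization: dict[str, tuple[float, float]] | None = None
    coefficient_se: tuple[float, ...] | None = None
    intercept_se: float | None = None

    def __post_init__(self) -> None:
        if len(self.descriptor_names) != len(self.coefficients):
            raise ValidationError("one coefficient per descriptor required")
        if self.standardization is not None:
            for name, (_, sd) in self.standardization.items():
                if sd <= 0:
                    raise ValidationError(f"nonpositive sd stored for {name!r}")

    @property
    def k(self) -> int:
        return len(self.descriptor_names)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "descriptor_names": list(self.descriptor_names),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "standardization": (
                None
                if self.standardization is None
                else {k: list(v) for k, v in self.standardization.items()}
            ),
            "coefficient_se": None
            if self.coefficient_se is None
            else list(self.coefficient_se),
            "intercept_se": self.intercept_se,
            "note": "OLS multiple linear regression on standardized descriptors",
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MLRModel":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and Path(source).exists()):
            source = Path(source).read_text()
        payload = json.loads(source)
        return cls(
            descriptor_names=tuple(payload["descriptor_names"]),
            coefficients=tuple(payload["coefficients"]),
            intercept=payload["intercept"],
            standardization=(
                None
                if payload["standardization"] is None
                else {k: tuple(v) for k, v in payload["standardization"].items()}
            ),
            coefficient_se=(
                None
                if payload.get("coefficient_se") is None
                else tuple(payload["coefficient_se"])
            ),
            intercept_se=payload.get("intercept_se"),
        )


@dataclass(frozen=True)
class ValidationReport:
    """Internal/external regression quality metrics (log10 units for MAE)."""

    r2_adj: float
    q2_loo: float
    mae95_train: float
    q2_f1: float | None = None
    q2_f2: float | None = None
    mae95_test: float | None = None
    external_defined: bool = True


@dataclass(frozen=True)
class ADReport:
    """Leverage / standardized-residual applicability-domain characteristics."""

    leverages: np.ndarray
    h_star: float
    std_residuals: np.ndarray
    outlier_flags: np.ndarray

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_flags.sum())


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test index lists covering all samples."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    method: str = "kennard_stone"

    def __post_init__(self) -> None:
        train, test = set(self.train_indices), set(self.test_indices)
        if train & test:
            raise ValidationError("train and test indices overlap")


# ---------------------------------------------------------------------------
# preprocessing


def standardize(
    table: DescriptorTable | pd.DataFrame,
) -> tuple[DescriptorTable, dict[str, tuple[float, float]]]:
    """Zero-mean, unit-(sample)-sd scaling of every descriptor column.

    Returns the scaled table and the per-descriptor (mean, sd) parameters for
    prediction-time reuse.  A constant column is an error (named).
    """
    frame = _as_frame(table)
    params: dict[str, tuple[float, float]] = {}
    out = {}
    for name in frame.columns:
        col = frame[name].to_numpy(dtype=float)
        mu, sd = float(col.mean()), float(col.std(ddof=1))
        if sd <= 0 or not math.isfinite(sd):
            raise FitError(f"descriptor {name!r} has zero variance")
        params[name] = (mu, sd)
        out[name] = (col - mu) / sd
    scaled = pd.DataFrame(out, index=frame.index)[frame.columns]
    response = table.response if isinstance(table, DescriptorTable) else None
    return DescriptorTable(frame=scaled, response=response), params


def correlation_filter(
    table: DescriptorTable | pd.DataFrame, r2_threshold: float = 0.5
) -> DescriptorTable:
    """Drop inter-correlated descriptors until no pair has R² > threshold.

    Deterministic greedy rule: repeatedly remove the descriptor with the most
    above-threshold partners, breaking ties by larger mean |r| to the
    remaining descriptors, then by column order.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise DomainError("r2_threshold must lie in (0, 1]")
    frame = _as_frame(table)
    names = list(frame.columns)
    corr = frame.corr().to_numpy()
    np.fill_diagonal(corr, 0.0)
    r2 = np.nan_to_num(corr**2, nan=0.0)
    alive = list(range(len(names)))
    while True:
        sub = r2[np.ix_(alive, alive)]
        over = sub > r2_threshold
        counts = over.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        worst = counts.max()
        candidates = [i for i, c in enumerate(counts) if c == worst]
        mean_abs_r = np.abs(corr[np.ix_(alive, alive)]).mean(axis=1)
        candidates.sort(key=lambda i: (-mean_abs_r[i], alive[i]))
        alive.pop(candidates[0])
    kept = [names[i] for i in alive]
    response = table.response if isinstance(table, DescriptorTable) else None
    return DescriptorTable(frame=frame[kept].copy(), response=response)


def kennard_stone(
    table: DescriptorTable | pd.DataFrame, train_fraction: float = 0.8
) -> SplitPlan:
    """Deterministic Kennard–Stone max-min train/test split.

    Works in standardized descriptor space: the first two training samples
    are the pair at maximal Euclidean distance, and each further sample
    maximizes its minimum distance to the already-selected set, until
    round(train_fraction·n) samples are selected.  Ties break to the lowest
    row index, making the split a pure function of row order.
    """
    frame = _as_frame(table)
    n = len(frame)
    if n < 2:
        raise DomainError("Kennard-Stone needs at least two samples")
    if not 0.0 < train_fraction <= 1.0:
        raise DomainError("train_fraction must lie in (0, 1]")
    n_train = int(round(train_fraction * n))
    n_train = max(2, min(n, n_train))
    X = frame.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    diff = Z[:, None, :] - Z[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    # maximal-distance pair, lowest indices on ties
    best = np.unravel_index(np.argmax(dist), dist.shape)
    selected = [min(best), max(best)]
    remaining = [i for i in range(n) if i not in selected]
    while len(selected) < n_train and remaining:
        min_d = dist[np.ix_(remaining, selected)].min(axis=1)
        pick = remaining[int(np.argmax(min_d))]  # argmax returns first max => lowest index
        selected.append(pick)
        remaining.remove(pick)
    if not remaining:
        warnings.warn("Kennard-Stone split has an empty test set", stacklevel=2)
    return SplitPlan(
        train_indices=tuple(selected), test_indices=tuple(remaining),
        method="kennard_stone",
    )


# ---------------------------------------------------------------------------
# fitting and prediction


def fit_mlr(
    X: DescriptorTable | pd.DataFrame,
    y: Sequence[float] | pd.Series | None = None,
    subset: Sequence[str] | None = None,
    standardization: dict[str, tuple[float, float]] | None = None,
) -> MLRModel:
    """Ordinary least squares with intercept on the named descriptor subset.

    ``X`` is expected already standardized; pass the parameters returned by
    :func:`standardize` to embed them in the model for prediction-time reuse.
    Rank deficiency raises :class:`FitError`.
    """
    frame = _as_frame(X)
    if y is None and isinstance(X, DescriptorTable):
        y = X.response
    if y is None:
        raise ValidationError("response y is required")
    yv = np.asarray(y, dtype=float)
    names = tuple(subset) if subset is not None else tuple(frame.columns)
    missing = [n for n in names if n not in frame.columns]
    if missing:
        raise ValidationError(f"subset descriptors not in table: {missing}")
    M = frame[list(names)].to_numpy(dtype=float)
    n, k = M.shape
    if n <= k + 1:
        raise FitError(f"need n > k+1 samples (n={n}, k={k})")
    design = np.column_stack([np.ones(n), M])
    beta, _, rank, _ = np.linalg.lstsq(design, yv, rcond=None)
    if rank < k + 1:
        raise FitError("design matrix is rank-deficient")
    resid = yv - design @ beta
    dof = n - k - 1
    sigma2 = float(resid @ resid) / dof if dof > 0 else float("nan")
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    std = None
    if standardization is not None:
        std = {name: tuple(standardization[name]) for name in names}
    return MLRModel(
        descriptor_names=names,
        coefficients=tuple(float(b) for b in beta[1:]),
        intercept=float(beta[0]),
        standardization=std,
        coefficient_se=tuple(float(s) for s in se[1:]),
        intercept_se=float(se[0]),
    )


def _design_for(model: MLRModel, descriptors, standardized: bool) -> np.ndarray:
    if isinstance(descriptors, (DescriptorTable, pd.DataFrame)):
        frame = _as_frame(descriptors)
        missing = [n for n in model.descriptor_names if n not in frame.columns]
        if missing:
            raise ValidationError(f"missing descriptor(s): {missing}")
        M = frame[list(model.descriptor_names)].to_numpy(dtype=float)
    elif isinstance(descriptors, Mapping):
        missing = [n for n in model.descriptor_names if n not in descriptors]
        if missing:
            raise ValidationError(f"missing descriptor(s): {missing}")
        M = np.array([[float(descriptors[n]) for n in model.descriptor_names]])
    else:
        M = np.atleast_2d(np.asarray(descriptors, dtype=float))
        if M.shape[1] != model.k:
            raise ValidationError(
                f"expected {model.k} descriptor values, got {M.shape[1]}"
            )
    if not standardized:
        if model.standardization is None:
            raise DomainError(
                "model standardization is external; supply standardized descriptors"
            )
        mu = np.array([model.standardization[n][0] for n in model.descriptor_names])
        sd = np.array([model.standardization[n][1] for n in model.descriptor_names])
        M = (M - mu) / sd
    return M


def predict(model: MLRModel, descriptors, standardized: bool = True) -> np.ndarray | float:
    """Predicted log10 saturation mole fraction(s) for the given descriptors.

    ``descriptors`` may be a mapping name→value (returns a scalar), a
    DataFrame/DescriptorTable, or a bare array ordered as the model's
    descriptors.  With ``standardized=False`` the model's stored
    standardization is applied first.
    """
    M = _design_for(model, descriptors, standardized)
    out = model.intercept + M @ np.asarray(model.coefficients)
    if isinstance(descriptors, Mapping):
        return float(out[0])
    return out


def published_edaravone_model() -> MLRModel:
    """The literature six-descriptor MLR for edaravone solubility in DES.

    log10(x_E) = 0.1722·EEtot + 0.5324·EEmisfit − 1.2071·μE + 0.7958·pot2inv
    + 0.3588·HBA + 0.1363·GrAB3 − 1.1069, on standardized descriptors
    (standardization performed externally, on the original 72-point dataset
    that was never published).  EEtot/EEmisfit are the solute's total and
    misfit interaction energies in the mixture, μE its chemical potential,
    pot2inv a σ-potential inverse-relative-curve descriptor, HBA the
    hydrogen-bond-acceptor region measure and GrAB3 the Gibbs energy of the
    drug–water association.
    """
    return MLRModel(
        descriptor_names=("EEtot", "EEmisfit", "muE", "pot2inv", "HBA", "GrAB3"),
        coefficients=(0.1722, 0.5324, -1.2071, 0.7958, 0.3588, 0.1363),
        intercept=-1.1069,
        standardization=None,
        coefficient_se=(0.0124, 0.0125, 0.0252, 0.0156, 0.0104, 0.0117),
        intercept_se=0.0051,
    )


# ---------------------------------------------------------------------------
# metrics


def mae95(residuals: Sequence[float], trim: float = 0.05) -> float:
    """Trimmed mean absolute error: drop the ceil(trim·n) largest |residuals|.

    The degenerate n=1 case discards its only residual and is defined as 0
    (with a warning).
    """
    res = np.abs(np.asarray(residuals, dtype=float))
    if res.size == 0:
        raise DomainError("mae95 needs at least one residual")
    n_drop = math.ceil(trim * res.size)
    kept = np.sort(res)[: res.size - n_drop] if n_drop else np.sort(res)
    if kept.size == 0:
        warnings.warn("all residuals trimmed; MAE95 defined as 0", stacklevel=2)
        return 0.0
    return float(kept.mean())


def _predict_matrix(model: MLRModel, frame: pd.DataFrame) -> np.ndarray:
    return np.asarray(predict(model, frame, standardized=True), dtype=float)


def validate(
    model: MLRModel,
    X_train: DescriptorTable | pd.DataFrame,
    y_train: Sequence[float],
    X_test: DescriptorTable | pd.DataFrame | None = None,
    y_test: Sequence[float] | None = None,
) -> ValidationReport:
    """Internal and external validation of a fitted MLR model.

    R²adj = 1 − (1 − R²)(n−1)/(n−k−1); Q²_LOO uses the leave-one-out PRESS
    (via the hat-matrix identity, exactly equal to refitting n times);
    Q²_F1 = 1 − Σ_test(y−ŷ)²/Σ_test(y−ȳ_train)² and Q²_F2 uses ȳ_test in
    the denominator.  With no test set the external metrics are None and
    ``external_defined`` is False.
    """
    ftr = _as_frame(X_train)
    ytr = np.asarray(y_train, dtype=float)
    n, k = len(ftr), model.k
    yhat = _predict_matrix(model, ftr)
    resid = ytr - yhat
    ss_res = float(resid @ resid)
    ss_tot = float(((ytr - ytr.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    # LOO PRESS via hat diagonal of the (intercept-augmented) training design
    design = np.column_stack([np.ones(n), ftr[list(model.descriptor_names)].to_numpy(float)])
    H = design @ np.linalg.inv(design.T @ design) @ design.T
    h = np.diag(H)
    loo_resid = resid / (1.0 - h)
    press = float(loo_resid @ loo_resid)
    q2_loo = 1.0 - press / ss_tot
    mae_train = mae95(resid)
    if X_test is None or y_test is None or len(_as_frame(X_test)) == 0:
        return ValidationReport(
            r2_adj=r2_adj, q2_loo=q2_loo, mae95_train=mae_train,
            external_defined=False,
        )
    fte = _as_frame(X_test)
    yte = np.asarray(y_test, dtype=float)
    resid_te = yte - _predict_matrix(model, fte)
    ss_res_te = float(resid_te @ resid_te)
    q2_f1 = 1.0 - ss_res_te / float(((yte - ytr.mean()) ** 2).sum())
    q2_f2 = 1.0 - ss_res_te / float(((yte - yte.mean()) ** 2).sum())
    return ValidationReport(
        r2_adj=r2_adj, q2_loo=q2_loo, mae95_train=mae_train,
        q2_f1=q2_f1, q2_f2=q2_f2, mae95_test=mae95(resid_te),
    )


# ---------------------------------------------------------------------------
# model search


def exhaustive_search(
    table: DescriptorTable | pd.DataFrame,
    y: Sequence[float] | None,
    split: SplitPlan,
    k: int,
    top_m: int = 10,
    combination_cap: int = 500_000,
    standardization: dict[str, tuple[float, float]] | None = None,
) -> list[tuple[MLRModel, ValidationReport]]:
    """Fit every k-descriptor subset on the training rows; rank by MAE95(test).

    Rank-deficient subsets are skipped.  The ranking is deterministic and
    independent of enumeration order: ties in the score break by the subset's
    descriptor-name tuple.
    """
    frame = _as_frame(table)
    if y is None and isinstance(table, DescriptorTable):
        y = table.response
    yv = np.asarray(y, dtype=float)
    names = list(frame.columns)
    n_comb = math.comb(len(names), k)
    if n_comb > combination_cap:
        raise DomainError(
            f"{n_comb} subsets exceed the cap {combination_cap}; raise the cap or "
            "filter descriptors first"
        )
    train, test = list(split.train_indices), list(split.test_indices)
    Xtr, Xte = frame.iloc[train], frame.iloc[test]
    ytr, yte = yv[train], yv[test]
    scored: list[tuple[float, tuple[str, ...], MLRModel, ValidationReport]] = []
    for combo in itertools.combinations(names, k):
        try:
            model = fit_mlr(Xtr, ytr, subset=combo, standardization=standardization)
        except FitError:
            continue
        report = validate(model, Xtr, ytr, Xte if len(test) else None,
                          yte if len(test) else None)
        score = report.mae95_test if report.external_defined else report.mae95_train
        scored.append((score, combo, model, report))
    scored.sort(key=lambda item: (item[0], item[1]))
    return [(model, report) for _, _, model, report in scored[:top_m]]


def size_scan(
    table: DescriptorTable | pd.DataFrame,
    y: Sequence[float] | None,
    split: SplitPlan,
    k_range: Iterable[int],
    top_m: int = 1,
    combination_cap: int = 500_000,
) -> pd.DataFrame:
    """Best MAE95 train/test per model size k (the model-size selection curve)."""
    rows = []
    for k in sorted(k_range):
        ranked = exhaustive_search(
            table, y, split, k, top_m=top_m, combination_cap=combination_cap
        )
        if not ranked:
            continue
        best_by_train = min(r.mae95_train for _, r in ranked)
        _, best_report = ranked[0]
        rows.append(
            {
                "k": k,
                "best_mae95_test": best_report.mae95_test,
                "best_mae95_train": best_by_train,
                "n_models_kept": len(ranked),
            }
        )
    return pd.DataFrame(rows).set_index("k")


# ---------------------------------------------------------------------------
# applicability domain


def applicability_domain(
    model: MLRModel,
    X_train: DescriptorTable | pd.DataFrame,
    y_train: Sequence[float],
    X_eval: DescriptorTable | pd.DataFrame | None = None,
    y_eval: Sequence[float] | None = None,
    h_star_convention: str = "printed",
) -> ADReport:
    """Williams-plot leverage / standardized-residual analysis.

    Leverage h_i = x_iᵀ(XᵀX)⁻¹x_i with an intercept column on the training
    design.  The cutoff h* is 3(k−1)/N under the 'printed' convention used in
    the source study, or the conventional 3(k+1)/N under 'standard'.
    Standardized residuals divide by the training residual sd; samples with
    |standardized residual| > 3 are flagged as outliers.
    """
    ftr = _as_frame(X_train)
    ytr = np.asarray(y_train, dtype=float)
    N, k = len(ftr), model.k
    cols = list(model.descriptor_names)
    design_tr = np.column_stack([np.ones(N), ftr[cols].to_numpy(float)])
    try:
        xtx_inv = np.linalg.inv(design_tr.T @ design_tr)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular training design") from exc
    if h_star_convention == "printed":
        h_star = 3.0 * (k - 1) / N
    elif h_star_convention == "standard":
        h_star = 3.0 * (k + 1) / N
    else:
        raise DomainError(f"unknown h* convention {h_star_convention!r}")
    resid_tr = ytr - _predict_matrix(model, ftr)
    dof = N - k - 1
    sd = float(np.sqrt(resid_tr @ resid_tr / dof)) if dof > 0 else float("nan")
    if X_eval is None:
        feval, resid = ftr, resid_tr
    else:
        feval = _as_frame(X_eval)
        if y_eval is None:
            raise ValidationError("y_eval required with X_eval")
        resid = np.asarray(y_eval, dtype=float) - _predict_matrix(model, feval)
    design_ev = np.column_stack([np.ones(len(feval)), feval[cols].to_numpy(float)])
    leverages = np.einsum("ij,jk,ik->i", design_ev, xtx_inv, design_ev)
    std_resid = resid / sd if sd > 0 else np.zeros_like(resid)
    return ADReport(
        leverages=leverages,
        h_star=h_star,
        std_residuals=std_resid,
        outlier_flags=np.abs(std_resid) > 3.0,
    )
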