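"""Validation of the conversion algorithm on paired prevalence data.

Paired prevalence records (one group observed under two cut-offs A and B) are
stacked and fitted with the no-intercept probit regression

    g(p_B) = Z_A + b * dz + eps,      g(p) = -sign(z_B) * PHI^-1(p)

where Z_A is an offset (the probit of the observed prevalence under A), dz is
the cut-off distance, and b defaults to 1 (the pure shift assumption).  Counts
are modelled as beta-binomial with intra-class correlation rho = c * |dz|
(c >= 0 estimated), so records with dz = 0 collapse to plain binomial and the
extrapolation error grows with the distance between the cut-offs.

Residual summaries compare the SD of observed-minus-predicted prevalence
(RSD) against the baseline SD of p_A - p_B (the "no conversion" model), with

    variance explained (%) = 100 * (1 - (RSD / baseline SD)**2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import betabinom, binom, norm

from .conversion import Z_to_prevalence, category_sign, prevalence_to_Z
from .distance import lookup_dz
from .reference import CATEGORIES, CutoffRegistry, ParseError, normalize_sex

__all__ = [
    "PairedPrevalenceRecord",
    "ValidationFit",
    "ResidualSummary",
    "DATASET_COLUMNS",
    "read_dataset_csv",
    "write_dataset_csv",
    "stack_records",
    "fit_slope",
    "mean_grouped_slopes",
    "variance_explained",
    "residual_summary",
    "bland_altman",
]

DATASET_COLUMNS = [
    "group", "source", "sex", "mean_age", "n", "category",
    "cutoff_A", "cutoff_B", "prev_A", "prev_B", "overweight_is_net",
]

_RHO_MAX = 0.999
_RHO_BINOM = 1e-9


@dataclass(frozen=True)
class PairedPrevalenceRecord:
    """One group's prevalences under two cut-offs, with probits and dz.

    Prevalences are proportions, overweight inclusive of obesity.  Records are
    normally oriented so dz > 0 (the main-analysis view); :meth:`flipped`
    gives the other orientation with dz negated and the A/B roles swapped.
    """

    group: str
    source: str
    sex: str
    mean_age: float
    n: int
    category: str
    label_A: str
    label_B: str
    p_A: float
    p_B: float
    dz: float
    Z_A: float
    Z_B: float

    @property
    def sign(self) -> int:
        return category_sign(self.category)

    @property
    def dZ(self) -> float:
        """Observed probit difference; equals dz in expectation under the
        pure-shift assumption."""
        return self.Z_B - self.Z_A

    def flipped(self) -> "PairedPrevalenceRecord":
        return replace(
            self,
            label_A=self.label_B, label_B=self.label_A,
            p_A=self.p_B, p_B=self.p_A,
            Z_A=self.Z_B, Z_B=self.Z_A,
            dz=-self.dz,
        )


def read_dataset_csv(path) -> pd.DataFrame:
    """Read a grouped prevalence dataset (prevalences in percent)."""
    df = pd.read_csv(Path(path))
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df.loc[:, DATASET_COLUMNS]


def write_dataset_csv(df: pd.DataFrame, path) -> None:
    df.loc[:, DATASET_COLUMNS].to_csv(path, index=False)


def _truthy(val) -> bool:
    if isinstance(val, str):
        return val.strip().lower() in ("1", "true", "yes", "y")
    return bool(val) and not pd.isna(val)


def _apply_net_overweight(df: pd.DataFrame, registry: CutoffRegistry) -> pd.DataFrame:
    """Add obesity prevalence onto net-overweight rows (same group/source and
    the same pair of references)."""
    df = df.copy()
    net = df[(df["category"] == "overweight")
             & df["overweight_is_net"].map(_truthy)]
    if net.empty:
        return df
    if registry is None:
        raise ValueError(
            "dataset contains net-of-obesity overweight rows; a cut-off "
            "registry is required to pair them with their obesity rows"
        )

    def refpair(row):
        a = registry.resolve(row["cutoff_A"], row["sex"], row["mean_age"])
        b = registry.resolve(row["cutoff_B"], row["sex"], row["mean_age"])
        return a.reference, b.reference

    errors = []
    for idx, row in net.iterrows():
        want = refpair(row)
        ob = df[(df["group"] == row["group"]) & (df["source"] == row["source"])
                & (df["category"] == "obesity")]
        ob = ob[[refpair(r) == want for _, r in ob.iterrows()]]
        if len(ob) != 1:
            errors.append(
                f"group {row['group']}: expected exactly one obesity row "
                f"matching references {want}, found {len(ob)}"
            )
            continue
        df.loc[idx, "prev_A"] = row["prev_A"] + float(ob["prev_A"].iloc[0])
        df.loc[idx, "prev_B"] = row["prev_B"] + float(ob["prev_B"].iloc[0])
        df.loc[idx, "overweight_is_net"] = False
    if errors:
        raise ValueError("net overweight rows could not be resolved:\n"
                         + "\n".join(errors))
    return df


def stack_records(
    dataset: pd.DataFrame,
    table: pd.DataFrame,
    registry: CutoffRegistry | None = None,
    both_orientations: bool = False,
) -> list[PairedPrevalenceRecord]:
    """Stack a grouped dataset into one record per (group x cut-off pair).

    Each record is oriented so dz > 0; with ``both_orientations`` the flipped
    records are appended as well (twice the points).  Prevalence columns are
    percent; net overweight rows are made inclusive of obesity first.
    Row-level problems are collected and reported together.
    """
    df = _apply_net_overweight(dataset, registry)
    records: list[PairedPrevalenceRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            sex = normalize_sex(row["sex"])
            category = str(row["category"])
            if category not in CATEGORIES:
                raise ValueError(f"unknown category {category!r}")
            n = int(row["n"])
            if n < 1:
                raise ValueError("count n must be >= 1")
            p_A = float(row["prev_A"]) / 100.0
            p_B = float(row["prev_B"]) / 100.0
            if np.isnan(p_A) or np.isnan(p_B):
                raise ValueError("missing prevalence")
            if not (0 <= p_A <= 1 and 0 <= p_B <= 1):
                raise ValueError("prevalence outside [0, 100]%")
            dz = lookup_dz(table, (row["cutoff_A"], row["cutoff_B"]),
                           sex, float(row["mean_age"]))
            sign = category_sign(category)
            rec = PairedPrevalenceRecord(
                group=str(row["group"]), source=str(row["source"]), sex=sex,
                mean_age=float(row["mean_age"]), n=n, category=category,
                label_A=str(row["cutoff_A"]), label_B=str(row["cutoff_B"]),
                p_A=p_A, p_B=p_B, dz=float(dz),
                Z_A=prevalence_to_Z(p_A, sign, n=n),
                Z_B=prevalence_to_Z(p_B, sign, n=n),
            )
            if rec.dz < 0:
                rec = rec.flipped()
            records.append(rec)
        except (ValueError, KeyError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValueError("dataset rows could not be stacked:\n" + "\n".join(errors))
    if both_orientations:
        records = records + [r.flipped() for r in records]
    return records


# ---------------------------------------------------------------------------
# Beta-binomial probit regression (Eq 4 structure)
# ---------------------------------------------------------------------------

@dataclass
class ValidationFit:
    """Fitted slope(s) of the probit regression with dispersion and fit scores.

    ``b``/``ci`` describe the single slope for the fixed/common models;
    ``b_by_cell``/``ci_by_cell`` the per-(source, category) slopes of the
    grouped model.  ``dispersion`` is c in rho = c*|dz|.
    """

    model: str
    error_model: str
    n_records: int
    loglik: float
    bic: float
    dispersion: float
    rsd_z: float
    b: float | None = None
    ci: tuple[float, float] | None = None
    b_by_cell: dict[tuple[str, str], float] | None = None
    ci_by_cell: dict[tuple[str, str], tuple[float, float]] | None = None

    @property
    def slopes(self) -> list[float]:
        if self.b_by_cell is not None:
            return [self.b_by_cell[k] for k in sorted(self.b_by_cell)]
        return [self.b]


def _record_arrays(records: Sequence[PairedPrevalenceRecord]):
    y = np.array([round(r.p_B * r.n) for r in records], dtype=float)
    n = np.array([r.n for r in records], dtype=float)
    Z_A = np.array([r.Z_A for r in records])
    dz = np.array([r.dz for r in records])
    sign = np.array([r.sign for r in records], dtype=float)
    return y, n, Z_A, dz, sign


def _loglik(b_per_record, c, y, n, Z_A, dz, sign) -> float:
    pi = norm.cdf(-sign * (Z_A + b_per_record * dz))
    pi = np.clip(pi, 1e-12, 1.0 - 1e-12)
    rho = np.clip(c * np.abs(dz), 0.0, _RHO_MAX)
    ll = np.empty_like(pi)
    bb = rho > _RHO_BINOM
    if np.any(~bb):
        ll[~bb] = binom.logpmf(y[~bb], n[~bb], pi[~bb])
    if np.any(bb):
        k = 1.0 / rho[bb] - 1.0
        ll[bb] = betabinom.logpmf(y[bb], n[bb], pi[bb] * k, (1.0 - pi[bb]) * k)
    return float(np.sum(ll))


def _numeric_hessian(fun, x, step=1e-4):
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_slope(
    records: Sequence[PairedPrevalenceRecord],
    model: str = "common_slope",
    error_model: str = "beta_binomial_absdz",
) -> ValidationFit:
    """Maximum-likelihood fit of the no-intercept probit conversion model.

    ``model``: 'fixed_b1' evaluates the likelihood at b = 1 (the algorithm as
    published), 'common_slope' estimates one b, 'grouped_slopes' one b per
    (source, category) cell.  ``error_model``: 'beta_binomial_absdz' estimates
    the dispersion coefficient c in rho = c*|dz|; 'binomial' fixes c = 0.
    95% CIs are Wald intervals from the observed information.
    """
    records = list(records)
    if len(records) < (1 if model == "fixed_b1" else 2):
        raise ValueError("too few records to fit")
    if model not in ("fixed_b1", "common_slope", "grouped_slopes"):
        raise ValueError(f"unknown model {model!r}")
    if error_model not in ("beta_binomial_absdz", "binomial"):
        raise ValueError(f"unknown error model {error_model!r}")
    y, n, Z_A, dz, sign = _record_arrays(records)
    if not np.all(np.abs(n - np.round(n)) < 1e-9):
        raise ValueError("denominators n must be integers")
    if model != "fixed_b1" and np.max(np.abs(dz)) < 1e-8:
        raise ValueError("all dz ~ 0: the slope is unidentifiable")

    if model == "grouped_slopes":
        cells = sorted({(r.source, r.category) for r in records})
        cell_idx = np.array(
            [cells.index((r.source, r.category)) for r in records]
        )
        n_b = len(cells)
    else:
        cells = None
        cell_idx = np.zeros(len(records), dtype=int)
        n_b = 0 if model == "fixed_b1" else 1

    estimate_c = error_model == "beta_binomial_absdz"
    c_max = _RHO_MAX / max(np.max(np.abs(dz)), 1e-8)

    def unpack(x):
        b_vec = x[:n_b] if n_b else np.array([1.0])
        c = x[n_b] if estimate_c else 0.0
        return b_vec, c

    def negll(x):
        b_vec, c = unpack(x)
        return -_loglik(b_vec[cell_idx], c, y, n, Z_A, dz, sign)

    x0 = np.concatenate([np.ones(n_b), [0.1] if estimate_c else []])
    bounds = [(-10.0, 10.0)] * n_b + ([(0.0, c_max)] if estimate_c else [])
    k_free = n_b + (1 if estimate_c else 0)

    if k_free == 0:
        x_hat = np.array([])
        ll = _loglik(np.ones(len(records)), 0.0, y, n, Z_A, dz, sign)
    else:
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        x_hat = res.x
        ll = -float(res.fun)

    b_vec, c_hat = unpack(x_hat) if k_free else (np.array([1.0]), 0.0)
    bic = k_free * np.log(len(records)) - 2.0 * ll

    # Wald CIs from the observed information; when c sits at its zero
    # boundary it is dropped from the Hessian (the curvature is one-sided).
    ses = np.full(n_b, np.nan)
    if n_b:
        free = list(range(n_b))
        if estimate_c and c_hat > 1e-6:
            free.append(n_b)

        def negll_sub(xs):
            full = x_hat.copy()
            full[free] = xs
            return negll(full)

        H = _numeric_hessian(negll_sub, x_hat[free])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        var = np.clip(np.diag(cov)[:n_b], 0.0, np.inf)
        ses = np.sqrt(var)

    resid_z = (np.array([r.Z_B for r in records]) - Z_A
               - b_vec[cell_idx] * dz)
    rsd_z = float(np.sqrt(np.mean(resid_z ** 2)))

    fit = ValidationFit(
        model=model, error_model=error_model, n_records=len(records),
        loglik=ll, bic=float(bic), dispersion=float(c_hat), rsd_z=rsd_z,
    )
    if model == "grouped_slopes":
        fit.b_by_cell = {cells[i]: float(b_vec[i]) for i in range(n_b)}
        fit.ci_by_cell = {
            cells[i]: (float(b_vec[i] - 1.96 * ses[i]),
                       float(b_vec[i] + 1.96 * ses[i]))
            for i in range(n_b)
        }
    elif model == "common_slope":
        fit.b = float(b_vec[0])
        fit.ci = (float(b_vec[0] - 1.96 * ses[0]),
                  float(b_vec[0] + 1.96 * ses[0]))
    else:
        fit.b = 1.0
    return fit


def mean_grouped_slopes(slopes: Iterable[float]) -> float:
    """Equal-weight average of per-cell slopes (weights the sources equally,
    unlike the likelihood which weights by denominators)."""
    slopes = list(slopes)
    if not slopes:
        raise ValueError("no slopes to average")
    return float(np.mean(slopes))


# ---------------------------------------------------------------------------
# Residual summaries and Bland-Altman preparation
# ---------------------------------------------------------------------------

def variance_explained(rsd: float, baseline_sd: float) -> float:
    """100 * (1 - (RSD / baseline SD)**2)."""
    if baseline_sd <= 0:
        raise ValueError("baseline SD must be positive")
    return 100.0 * (1.0 - (rsd / baseline_sd) ** 2)


@dataclass
class ResidualSummary:
    """Residual SDs (percent scale) per category and overall.

    Each record contributes two residuals (A predicted from B and B from A),
    mirroring the both-orientations analysis; the baseline model predicts each
    prevalence by the other one unchanged.
    """

    b_used: float
    rsd_prev: dict[str, float]
    baseline_sd: dict[str, float]
    var_explained: dict[str, float]
    n_points: dict[str, int]


def _predictions(records, b):
    """Predicted (p_B from A, p_A from B) per record, as proportions."""
    preds = []
    for r in records:
        p_hat_B = Z_to_prevalence(r.Z_A + b * r.dz, r.sign)
        p_hat_A = Z_to_prevalence(r.Z_B - b * r.dz, r.sign)
        preds.append((p_hat_B, p_hat_A))
    return preds


def residual_summary(
    records: Sequence[PairedPrevalenceRecord], b: float = 1.0
) -> ResidualSummary:
    """RSD of observed minus predicted prevalence vs the baseline SD of
    p_A - p_B, per category and overall (percent scale)."""
    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    preds = _predictions(records, b)
    rows = []
    for r, (p_hat_B, p_hat_A) in zip(records, preds):
        rows.append((r.category, 100 * (r.p_B - p_hat_B), 100 * (r.p_A - r.p_B)))
        rows.append((r.category, 100 * (r.p_A - p_hat_A), 100 * (r.p_B - r.p_A)))
    df = pd.DataFrame(rows, columns=["category", "resid", "base"])

    def rms(v):
        return float(np.sqrt(np.mean(np.square(v))))

    rsd, base_sd, varexp, npts = {}, {}, {}, {}
    groups = {cat: sub for cat, sub in df.groupby("category")}
    groups["all"] = df
    for cat, sub in groups.items():
        rsd[cat] = rms(sub["resid"])
        base_sd[cat] = rms(sub["base"])
        varexp[cat] = (
            variance_explained(rsd[cat], base_sd[cat]) if base_sd[cat] > 0
            else float("nan")
        )
        npts[cat] = len(sub)
    return ResidualSummary(
        b_used=float(b), rsd_prev=rsd, baseline_sd=base_sd,
        var_explained=varexp, n_points=npts,
    )


def bland_altman(
    records: Sequence[PairedPrevalenceRecord], b: float = 1.0
) -> pd.DataFrame:
    """Plot-ready (mean, difference) pairs on the percent scale.

    kind 'algorithm': observed vs predicted prevalence, both directions;
    kind 'baseline': the raw pairs, plotted as +/-(p_A - p_B) vs their mean.
    """
    preds = _predictions(records, b)
    rows = []
    for r, (p_hat_B, p_hat_A) in zip(records, preds):
        common = dict(category=r.category, source=r.source, dz=r.dz)
        rows.append(dict(
            kind="algorithm", mean=50 * (r.p_B + p_hat_B),
            diff=100 * (r.p_B - p_hat_B), **common,
        ))
        rows.append(dict(
            kind="algorithm", mean=50 * (r.p_A + p_hat_A),
            diff=100 * (r.p_A - p_hat_A), **common,
        ))
        base_mean = 50 * (r.p_A + r.p_B)
        base_diff = 100 * (r.p_A - r.p_B)
        rows.append(dict(kind="baseline", mean=base_mean, diff=base_diff, **common))
        rows.append(dict(kind="baseline", mean=base_mean, diff=-base_diff, **common))
    return pd.DataFrame(rows, columns=["kind", "mean", "diff",
                                       "category", "source", "dz"])
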