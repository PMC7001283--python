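"""Flow-cytometry micronucleus (MN) and relative-survival (RS) statistics.

Endpoints per chemical:

* RS% from intact-nuclei-to-counting-bead ratios in exposed vs vehicle
  wells (mean-of-ratios convention);
* %MN from micronucleated events over scored cells;
* generalized estimating equations (GEE) with an independence working
  correlation and well-level clusters: binomial variance with a log link
  for MN, gaussian with an identity link for RS.  With one indicator per
  concentration the fit is saturated, so the group estimates are pooled
  proportions / means — a closed form used as a numerical self-check.
* delta-method back-transformation of log-link estimates to the MN% scale;
* the positivity rule: a concentration is MN-positive when the fold over
  the matched vehicle is at least twofold AND the Wald test is significant;
* cytotoxic-concentration exclusion (RS < 40%) and low/mid/high
  concentration selection for sequencing.

Robust (sandwich) and model-based covariances are both computed.  With
duplicate wells the sandwich has very few residual degrees of freedom per
group, so its normal-reference p-values are anti-conservative; the
model-based covariance is exact when counts really are binomial / normal.
Both are exposed; the positivity rule's twofold gate makes the final call
insensitive to the choice under realistic event counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_RS_CUTOFF = 40.0
DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_MN_ALPHA = 0.01
DEFAULT_RS_ALPHA = 0.05


class ConvergenceError(RuntimeError):
    pass


@dataclasses.dataclass
class GEEFit:
    """A fitted GEE for one chemical and endpoint.

    ``params`` holds the intercept (vehicle level on the link scale) and
    one coefficient per concentration index.  ``table`` holds the
    back-transformed per-concentration summary: estimate, SE (delta
    method), fold vs vehicle, fold SE and two-sided Wald p-value.
    """

    endpoint: str                    # "MN" | "RS"
    link: str                        # "log" | "identity"
    params: pd.Series
    cov_robust: pd.DataFrame
    cov_naive: pd.DataFrame
    table: pd.DataFrame
    converged: bool
    n_iter: int
    continuity_adjusted: list[int] = dataclasses.field(default_factory=list)
    df_resid: int = 0

    def __post_init__(self) -> None:
        for cov in (self.cov_robust, self.cov_naive):
            arr = cov.to_numpy()
            if not np.allclose(arr, arr.T, atol=1e-10):
                raise ValueError("covariance must be symmetric")


@dataclasses.dataclass
class MNResult:
    """Per-concentration MN decisions for one chemical.

    ``table`` columns: concentration_index, mn_pct, fold, p_value,
    excluded, positive.  Excluded (cytotoxic) concentrations carry no call.
    """

    chemical: str
    table: pd.DataFrame
    positive: bool
    excluded: list[int]


# ---------------------------------------------------------------------------
# simple endpoints


def mn_frequency(mn_events: int, scored_cells: int) -> float:
    """%MN of one well: 100 * events / scored cells."""
    if scored_cells <= 0:
        raise ValueError("scored_cells must be > 0")
    if mn_events < 0 or mn_events > scored_cells:
        raise ValueError("mn_events must lie in [0, scored_cells]")
    return 100.0 * mn_events / scored_cells


def relative_survival(wells: pd.DataFrame) -> pd.Series:
    """RS% per concentration index from nuclei-to-bead ratios.

    Mean over replicate wells of (nuclei / bead), divided by the mean
    vehicle ratio, times 100.  ``wells`` is one chemical's slice of the
    flow table.
    """
    if (wells["bead_count"] <= 0).any():
        raise ValueError("bead counts must be > 0")
    vehicle = wells[wells["is_vehicle"]]
    if vehicle.empty:
        chem = wells["chemical"].iloc[0] if len(wells) else "?"
        raise ValueError(f"no vehicle-control wells for chemical {chem!r}")
    ratio = wells["nuclei_count"] / wells["bead_count"]
    vehicle_mean = ratio[wells["is_vehicle"]].mean()
    treated = wells[~wells["is_vehicle"]]
    rs = (ratio[treated.index].groupby(treated["concentration_index"]).mean()
          / vehicle_mean * 100.0)
    rs.name = "rs_pct"
    return rs.sort_index()


# ---------------------------------------------------------------------------
# GEE machinery


def _design(conc_idx: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Saturated design: intercept + one indicator per concentration."""
    levels = sorted(set(conc_idx) - {0})
    X = np.zeros((len(conc_idx), 1 + len(levels)))
    X[:, 0] = 1.0
    for j, level in enumerate(levels, start=1):
        X[conc_idx == level, j] = 1.0
    names = ["intercept"] + [f"conc_{level}" for level in levels]
    return X, names


def _sandwich(A_inv: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """CR0 sandwich with an HC1-style small-sample factor N/(N-p)."""
    B = scores.T @ scores
    n, p = scores.shape
    factor = n / max(n - p, 1)
    return factor * A_inv @ B @ A_inv


def fit_gee_binomial_log(
    wells: pd.DataFrame, max_iter: int = 50, tol: float = 1e-8
) -> GEEFit:
    """GEE fit of MN counts: binomial variance, log link, well clusters.

    Solves sum_i D_i^T V_i^-1 (y_i - mu_i) = 0 by Fisher scoring with
    mu = exp(X beta) (per-cell MN probability) and working variance
    mu (1 - mu) / n_cells per well.  Groups with zero total events get a
    Haldane-style 0.5-event continuity adjustment spread over their wells,
    flagged in the diagnostics.
    """
    wells = _check_wells(wells)
    conc = wells["concentration_index"].to_numpy()
    X, names = _design(conc)
    n_cells = wells["scored_cells"].to_numpy(float)
    events = wells["mn_events"].to_numpy(float)

    adjusted: list[int] = []
    for level in sorted(set(conc)):
        mask = conc == level
        if events[mask].sum() == 0.0:
            events[mask] += 0.5 / mask.sum()
            adjusted.append(int(level))
    y = events / n_cells

    # start at the pooled-rate solution of the saturated model
    beta = np.zeros(X.shape[1])
    pooled0 = events[conc == 0].sum() / n_cells[conc == 0].sum()
    beta[0] = np.log(pooled0)
    for j, name in enumerate(names[1:], start=1):
        level = int(name.split("_")[1])
        rate = events[conc == level].sum() / n_cells[conc == level].sum()
        beta[j] = np.log(rate) - beta[0]

    converged = False
    for iteration in range(1, max_iter + 1):
        mu = np.exp(np.clip(X @ beta, -700, -1e-12))
        w = n_cells * mu / (1.0 - mu)            # X' diag(w) X is the scoring matrix
        resid = n_cells * (y - mu) / (1.0 - mu)  # per-well score weight on x_i
        U = X.T @ resid
        A = (X * w[:, None]).T @ X
        step = np.linalg.solve(A, U)
        beta = beta + step
        if np.max(np.abs(step) / (np.abs(beta) + 1.0)) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"GEE binomial/log failed to converge in {max_iter} iterations; "
            f"last step {np.max(np.abs(step)):.3g}")

    mu = np.exp(X @ beta)
    w = n_cells * mu / (1.0 - mu)
    A_inv = np.linalg.inv((X * w[:, None]).T @ X)
    scores = X * (n_cells * (y - mu) / (1.0 - mu))[:, None]
    cov_robust = _sandwich(A_inv, scores)

    fit = GEEFit(
        endpoint="MN", link="log",
        params=pd.Series(beta, index=names),
        cov_robust=pd.DataFrame(cov_robust, index=names, columns=names),
        cov_naive=pd.DataFrame(A_inv, index=names, columns=names),
        table=pd.DataFrame(),
        converged=True, n_iter=iteration, continuity_adjusted=adjusted,
        df_resid=max(len(wells) - X.shape[1], 1),
    )
    fit.table = delta_method_backtransform(fit)
    return fit


def fit_gee_normal_identity(wells: pd.DataFrame) -> GEEFit:
    """GEE fit of per-well RS%: gaussian, identity link, well clusters.

    The estimates are the group means; the sandwich covariance is built
    from well-level residuals.  Per-well RS is each well's nuclei/bead
    ratio relative to the mean vehicle ratio.
    """
    wells = _check_wells(wells)
    if len(wells) < 2:
        raise ValueError("need at least two wells")
    conc = wells["concentration_index"].to_numpy()
    X, names = _design(conc)
    ratio = (wells["nuclei_count"] / wells["bead_count"]).to_numpy(float)
    vehicle_mean = ratio[conc == 0].mean()
    y = 100.0 * ratio / vehicle_mean

    XtX = X.T @ X
    A_inv = np.linalg.inv(XtX)
    beta = A_inv @ X.T @ y
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = float(resid @ resid) / max(n - p, 1)
    cov_naive = sigma2 * A_inv
    cov_robust = _sandwich(A_inv, X * resid[:, None])

    fit = GEEFit(
        endpoint="RS", link="identity",
        params=pd.Series(beta, index=names),
        cov_robust=pd.DataFrame(cov_robust, index=names, columns=names),
        cov_naive=pd.DataFrame(cov_naive, index=names, columns=names),
        table=pd.DataFrame(),
        converged=True, n_iter=0, df_resid=max(n - p, 1),
    )
    fit.table = delta_method_backtransform(fit)
    return fit


def delta_method_backtransform(fit: GEEFit, se: str = "robust") -> pd.DataFrame:
    """Per-concentration estimates on the original scale.

    Log link: estimate = exp(eta), SE = exp(eta) * SE(eta) (first-order
    delta method), fold = exp(beta_c) with SE exp(beta_c) * SE(beta_c).
    Identity link: pass-through; "fold" is the difference from vehicle
    reported as estimate / vehicle for convenience.  P-values are
    two-sided Wald on the concentration coefficient: normal reference for
    the binomial log-link endpoint (the effective n is the cell count), t
    with the residual degrees of freedom for the gaussian identity-link
    endpoint (the effective n is the well count).
    """
    cov = fit.cov_robust if se == "robust" else fit.cov_naive
    names = list(fit.params.index)
    b0 = fit.params["intercept"]
    v00 = cov.loc["intercept", "intercept"]
    rows = []
    for name in names[1:]:
        level = int(name.split("_")[1])
        bc = fit.params[name]
        vcc = cov.loc[name, name]
        v0c = cov.loc["intercept", name]
        eta = b0 + bc
        se_eta = float(np.sqrt(max(v00 + vcc + 2.0 * v0c, 0.0)))
        se_bc = float(np.sqrt(max(vcc, 0.0)))
        if fit.link == "log":
            estimate = float(np.exp(eta))
            se_est = estimate * se_eta
            fold = float(np.exp(bc))
            fold_se = fold * se_bc
        else:
            estimate = float(eta)
            se_est = se_eta
            fold = float(eta / b0) if b0 != 0 else np.nan
            fold_se = np.nan
        z = bc / se_bc if se_bc > 0 else np.inf * np.sign(bc)
        if not np.isfinite(z):
            p = 0.0 if bc != 0 else 1.0
        elif fit.link == "identity":
            p = float(2.0 * stats.t.sf(abs(z), fit.df_resid))
        else:
            p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(dict(concentration_index=level, estimate=estimate,
                         se=se_est, fold=fold, fold_se=fold_se, p_value=p))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# decision rules


def mn_call(
    fit: GEEFit,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    alpha: float = DEFAULT_MN_ALPHA,
    excluded: set[int] | None = None,
    chemical: str = "",
) -> MNResult:
    """Positivity per concentration: fold >= threshold AND p < alpha.

    Cytotoxic (excluded) concentrations carry no call; the chemical is
    MN-positive when any retained concentration is positive.
    """
    if fit.endpoint != "MN":
        raise ValueError("mn_call needs an MN-endpoint fit")
    excluded = set(excluded or ())
    table = fit.table.copy()
    table["mn_pct"] = table["estimate"] * 100.0
    table["excluded"] = table["concentration_index"].isin(excluded)
    table["positive"] = (~table["excluded"]
                         & (table["fold"] >= fold_threshold)
                         & (table["p_value"] < alpha))
    cols = ["concentration_index", "mn_pct", "fold", "p_value",
            "excluded", "positive"]
    return MNResult(chemical=chemical, table=table[cols],
                    positive=bool(table["positive"].any()),
                    excluded=sorted(excluded))


def exclude_cytotoxic(rs: pd.Series, cutoff: float = DEFAULT_RS_CUTOFF
                      ) -> tuple[list[int], list[int]]:
    """Split concentration indices into (retained, removed) by RS < cutoff."""
    removed = sorted(int(i) for i, v in rs.items() if v < cutoff)
    retained = sorted(int(i) for i in rs.index if int(i) not in removed)
    if not retained:
        raise ValueError("all concentrations are cytotoxic; no analyzable range")
    return retained, removed


def select_concentrations(
    doses: pd.Series, cap: float | None = None
) -> dict[str, int]:
    """Pick the (low, mid, high) concentrations for expression profiling.

    ``doses`` maps retained concentration indices to dose values.  High is
    the highest retained dose (not above ``cap`` when one is given — in
    the absence of cytotoxicity the cap is 10 mM).  Low and mid are the
    retained pair whose log-doses sit closest to even thirds of the
    log-range below high; ties break toward the lower concentrations.
    """
    doses = doses.sort_index()
    if (doses <= 0).any():
        raise ValueError("doses must be positive")
    eligible = doses if cap is None else doses[doses <= cap]
    if len(eligible) < 3:
        raise ValueError("need at least three retained concentrations")
    high_idx = int(eligible.index[-1])
    below = eligible.iloc[:-1]
    if len(below) == 2:
        low_idx, mid_idx = (int(i) for i in below.index)
        return {"low": low_idx, "mid": mid_idx, "high": high_idx}

    log_d = np.log(below.to_numpy(float))
    log_hi = float(np.log(eligible.iloc[-1]))
    log_lo = float(log_d.min())
    span = log_hi - log_lo
    targets = (log_lo + span / 3.0, log_lo + 2.0 * span / 3.0)

    best = None
    idx = list(below.index)
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            cost = abs(log_d[a] - targets[0]) + abs(log_d[b] - targets[1])
            key = (cost, log_d[a], log_d[b])  # ties -> lower concentrations
            if best is None or key < best[0]:
                best = (key, int(idx[a]), int(idx[b]))
    return {"low": best[1], "mid": best[2], "high": high_idx}


def analyze_chemical(
    wells: pd.DataFrame,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    mn_alpha: float = DEFAULT_MN_ALPHA,
    rs_cutoff: float = DEFAULT_RS_CUTOFF,
) -> tuple[pd.Series, GEEFit, GEEFit, MNResult, list[int]]:
    """Full flow analysis of one chemical's wells.

    Returns (RS% series, MN fit, RS fit, MN result, retained indices).
    """
    chemical = str(wells["chemical"].iloc[0])
    rs = relative_survival(wells)
    retained, removed = exclude_cytotoxic(rs, cutoff=rs_cutoff)
    mn_fit = fit_gee_binomial_log(wells)
    rs_fit = fit_gee_normal_identity(wells)
    result = mn_call(mn_fit, fold_threshold=fold_threshold, alpha=mn_alpha,
                     excluded=set(removed), chemical=chemical)
    return rs, mn_fit, rs_fit, result, retained


def _check_wells(wells: pd.DataFrame) -> pd.DataFrame:
    required = {"chemical", "concentration_index", "scored_cells",
                "mn_events", "nuclei_count", "bead_count", "is_vehicle"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")
    if not wells["is_vehicle"].any():
        chem = wells["chemical"].iloc[0] if len(wells) else "?"
        raise ValueError(f"no vehicle-control wells for chemical {chem!r}")
    if (~wells["is_vehicle"]).sum() == 0:
        raise ValueError("no treated wells")
    if (wells["mn_events"] > wells["scored_cells"]).any():
        raise ValueError("mn_events cannot exceed scored_cells")
    if (wells[["scored_cells", "mn_events", "nuclei_count"]] < 0).any().any():
        raise ValueError("counts must be non-negative")
    if (wells["bead_count"] <= 0).any():
        raise ValueError("bead counts must be > 0")
    return wells
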