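"""Gaussian-mixture patient stratification over per-event PSI values.

For every splicing event, a univariate Gaussian mixture with 1 to 3
components is fitted by EM to the pooled PSI values of tumor and control
samples; the component count is selected by BIC and samples are assigned to
the maximum-posterior component.  Components that are almost entirely
tumor (>90% purity), large enough (>= 50 patients) and strongly shifted
against control tissues (|dPSI| >= 20 percentage points, Wilcoxon rank-sum)
are called tumor-specific subpopulations, and their overall survival is
compared by global and pairwise log-rank tests with Benjamini-Hochberg
adjustment (subpopulations of >= 30 patients, adjusted P < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .survival import logrank_test

_LOG_2PI = float(np.log(2.0 * np.pi))


# --- univariate EM engine ----------------------------------------------


class UnivariateGMM(BaseEstimator):
    """1-D Gaussian mixture fitted by EM with BIC model selection.

    Components ``k`` in 1..k_max are fitted with quantile-spaced mean
    initialization, a pooled-variance start, ``restarts`` jittered restarts
    (best log-likelihood kept), a variance floor, and convergence at a
    log-likelihood tolerance of ``tol``.  BIC uses 3k - 1 free parameters
    (unequal-variance model); the k with minimal BIC is selected.
    """

    def __init__(
        self,
        k_max: int = 3,
        variance_floor: float = 1e-4,
        tol: float = 1e-6,
        max_iter: int = 500,
        restarts: int = 5,
        random_state: int = 0,
    ):
        self.k_max = k_max
        self.variance_floor = variance_floor
        self.tol = tol
        self.max_iter = max_iter
        self.restarts = restarts
        self.random_state = random_state

    # internals ---------------------------------------------------------

    def _log_density(self, x, w, mu, var):
        # (n, k) component log densities + log weights
        return (
            np.log(w)[None, :]
            - 0.5 * (_LOG_2PI + np.log(var))[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )

    def _em_batch(self, x, k, mu0s):
        # all restarts advanced together as (restart, sample, component) arrays
        r, n = mu0s.shape[0], x.size
        w = np.full((r, k), 1.0 / k)
        mu = mu0s.copy()
        var = np.full((r, k), max(float(np.var(x)), self.variance_floor))
        loglik = np.full(r, -np.inf)
        active = np.ones(r, dtype=bool)
        xc = x[None, :, None]
        for _ in range(self.max_iter):
            idx = np.where(active)[0]
            if idx.size == 0:
                break
            wi, mi, vi = w[idx], mu[idx], var[idx]
            ld = (
                np.log(wi)[:, None, :]
                - 0.5 * (_LOG_2PI + np.log(vi))[:, None, :]
                - 0.5 * (xc - mi[:, None, :]) ** 2 / vi[:, None, :]
            )
            m = ld.max(axis=2, keepdims=True)
            lse = m[..., 0] + np.log(np.exp(ld - m).sum(axis=2))
            new_ll = lse.sum(axis=1)
            resp = np.exp(ld - lse[..., None])
            nk = np.maximum(resp.sum(axis=1), 1e-300)
            w[idx] = nk / n
            mu[idx] = (resp * xc).sum(axis=1) / nk
            var[idx] = np.maximum(
                (resp * (xc - mu[idx][:, None, :]) ** 2).sum(axis=1) / nk,
                self.variance_floor,
            )
            done = (new_ll - loglik[idx] < self.tol) & np.isfinite(loglik[idx])
            loglik[idx] = new_ll
            active[idx[done]] = False
        best = int(np.argmax(loglik))
        return float(loglik[best]), w[best], mu[best], var[best]

    def _fit_k(self, x, k, rng):
        if k == 1:
            # EM fixed point in closed form
            mu = np.array([float(np.mean(x))])
            var = np.array([max(float(np.var(x)), self.variance_floor)])
            loglik = float(
                -0.5 * x.size * (_LOG_2PI + np.log(var[0]))
                - 0.5 * np.sum((x - mu[0]) ** 2) / var[0]
            )
            return loglik, np.array([1.0]), mu, var
        qs = np.quantile(x, [(i + 1) / (k + 1) for i in range(k)])
        sd = max(float(np.std(x)), np.sqrt(self.variance_floor))
        mu0s = [qs]
        for _ in range(1, self.restarts):
            mu0s.append(np.sort(qs + rng.normal(0.0, sd / 2.0, size=k)))
        return self._em_batch(x, k, np.asarray(mu0s, dtype=float))

    # sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size == 0:
            raise ValueError("empty input")
        if not np.isfinite(x).all():
            raise ValueError("non-finite values")
        rng = np.random.default_rng(self.random_state)
        self.bic_: Dict[int, float] = {}
        fits = {}
        for k in range(1, self.k_max + 1):
            loglik, w, mu, var = self._fit_k(x, k, rng)
            n_params = 3 * k - 1
            self.bic_[k] = -2.0 * loglik + n_params * np.log(x.size)
            fits[k] = (loglik, w, mu, var)
        self.k_ = min(self.bic_, key=lambda k: (self.bic_[k], k))
        loglik, w, mu, var = fits[self.k_]
        order = np.argsort(mu)  # deterministic component labelling by mean
        self.weights_ = w[order]
        self.means_ = mu[order]
        self.sds_ = np.sqrt(var[order])
        self.loglik_ = loglik
        self.labels_ = self.predict(x)
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        ld = self._log_density(x, self.weights_, self.means_, self.sds_**2)
        return ld.argmax(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        ld = self._log_density(x, self.weights_, self.means_, self.sds_**2)
        m = ld.max(axis=1, keepdims=True)
        p = np.exp(ld - m)
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class GmmFit:
    event_id: str
    k_selected: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    bic: Dict[int, float]
    loglik: float
    sample_ids: List[str]
    values: np.ndarray
    assignments: Dict[str, int]


def fit_gmm(
    psi_values: Sequence[float],
    k_max: int = 3,
    seed: int = 0,
    event_id: str = "",
    min_samples: int = 10,
    **gmm_params,
) -> GmmFit:
    """Fit the per-event mixture on non-missing PSI values."""
    values = np.asarray(psi_values, dtype=float)
    ids = [str(i) for i in range(values.size)]
    if isinstance(psi_values, pd.Series):
        ids = [str(s) for s in psi_values.index]
    keep = ~np.isnan(values)
    values, ids = values[keep], [s for s, k in zip(ids, keep) if k]
    if values.size < min_samples:
        raise ValueError(
            f"{event_id or 'event'}: only {values.size} non-missing values "
            f"(< {min_samples})"
        )
    if not np.isfinite(values).all():
        raise ValueError("non-finite PSI")
    model = UnivariateGMM(k_max=k_max, random_state=seed, **gmm_params).fit(values)
    return GmmFit(
        event_id=event_id,
        k_selected=model.k_,
        weights=model.weights_,
        means=model.means_,
        sds=model.sds_,
        bic=model.bic_,
        loglik=model.loglik_,
        sample_ids=ids,
        values=values,
        assignments=dict(zip(ids, model.labels_.tolist())),
    )


# --- subpopulation summaries -------------------------------------------


@dataclass
class SubpopulationResult:
    event_id: str
    component_id: int
    n_tumor: int
    n_control: int
    purity: float
    delta_psi: float  # percentage points vs all control samples
    wilcoxon_p: float
    tumor_specific: bool
    mean_psi: float = float("nan")


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float], exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p value.

    Exact enumeration when both samples have <= ``exact_max_n``
    observations and no ties; otherwise the normal approximation with tie
    correction (no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= exact_max_n and y.size <= exact_max_n and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=False
        ).pvalue
    )


def summarize_subpopulations(
    fit: GmmFit,
    samples: pd.DataFrame,
    purity_min: float = 0.90,
    n_min: int = 50,
    delta_psi_min: float = 20.0,
    wilcoxon_gate: bool = True,
    wilcoxon_alpha: float = 0.05,
) -> List[SubpopulationResult]:
    """Per-component tumor/control composition, dPSI and Wilcoxon test.

    dPSI compares the tumor members of a component against *all* fitted
    control samples, in percentage points.  Raises when no control sample
    was fitted (the event cannot be assessed for tumor specificity).
    """
    group = samples.set_index("sample_id")["group"]
    sample_group = np.array([group.get(s, "tumor") for s in fit.sample_ids])
    control_psi = fit.values[sample_group == "control"]
    if control_psi.size == 0:
        raise ValueError(f"{fit.event_id}: no control samples fitted")
    assign = np.array([fit.assignments[s] for s in fit.sample_ids])
    out: List[SubpopulationResult] = []
    for comp in range(fit.k_selected):
        members = assign == comp
        is_tumor = sample_group == "tumor"
        n_tumor = int((members & is_tumor).sum())
        n_control = int((members & ~is_tumor).sum())
        if n_tumor + n_control == 0:
            continue
        purity = n_tumor / (n_tumor + n_control)
        tumor_psi = fit.values[members & is_tumor]
        if tumor_psi.size:
            delta = 100.0 * (float(tumor_psi.mean()) - float(control_psi.mean()))
            p = wilcoxon_rank_sum(tumor_psi, control_psi)
        else:
            delta, p = float("nan"), 1.0
        specific = (
            purity > purity_min
            and n_tumor >= n_min
            and abs(delta) >= delta_psi_min
            and (not wilcoxon_gate or p < wilcoxon_alpha)
        )
        out.append(
            SubpopulationResult(
                event_id=fit.event_id,
                component_id=comp,
                n_tumor=n_tumor,
                n_control=n_control,
                purity=purity,
                delta_psi=delta,
                wilcoxon_p=p,
                tumor_specific=bool(specific),
                mean_psi=float(fit.values[members].mean()),
            )
        )
    return out


# --- survival association ----------------------------------------------


@dataclass
class SurvivalResult:
    event_id: str
    component_i: int
    component_j: int
    logrank_chisq: float
    p: float
    adjusted_p: float
    global_p: float
    significant: bool


def pairwise_survival(
    fit: GmmFit,
    samples: pd.DataFrame,
    min_n: int = 30,
    alpha: float = 0.01,
) -> List[SurvivalResult]:
    """Global + pairwise log-rank tests between GMM subpopulations.

    Components with >= ``min_n`` tumor patients carrying survival data are
    eligible; pairwise p values are Benjamini-Hochberg adjusted within the
    event, and a pair is significant when the global p and its adjusted
    pairwise p are both below ``alpha``.
    """
    info = samples.set_index("sample_id")
    comp_data: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    for comp in range(fit.k_selected):
        t, e = [], []
        for s in fit.sample_ids:
            if fit.assignments[s] != comp or s not in info.index:
                continue
            row = info.loc[s]
            if row["group"] != "tumor" or pd.isna(row["survival_time"]) or pd.isna(
                row["event_observed"]
            ):
                continue
            t.append(float(row["survival_time"]))
            e.append(bool(row["event_observed"]))
        if len(t) >= min_n:
            comp_data[comp] = (np.asarray(t), np.asarray(e, dtype=bool))
    if len(comp_data) < 2:
        return []
    comps = sorted(comp_data)
    _, global_p = logrank_test([comp_data[c] for c in comps])
    pairs = list(combinations(comps, 2))
    raw = []
    chis = []
    for i, j in pairs:
        chisq, p = logrank_test([comp_data[i], comp_data[j]])
        raw.append(p)
        chis.append(chisq)
    adj = multipletests(raw, method="fdr_bh")[1]
    return [
        SurvivalResult(
            event_id=fit.event_id,
            component_i=i,
            component_j=j,
            logrank_chisq=chis[idx],
            p=raw[idx],
            adjusted_p=float(adj[idx]),
            global_p=global_p,
            significant=bool(global_p < alpha and adj[idx] < alpha),
        )
        for idx, (i, j) in enumerate(pairs)
    ]


# --- cohort-level driver -----------------------------------------------


def _event_type(event_id: str) -> str:
    try:
        return event_id.split(";", 1)[1].split(":", 1)[0]
    except IndexError:
        return "NA"


class GmmStratifier(BaseEstimator):
    """End-to-end per-event stratification over a PSI matrix.

    ``fit`` expects a PSI DataFrame (events x samples, NaN missing) and a
    clinical sample table; fitted attributes hold per-event mixture fits,
    subpopulation and survival tables, and a summary of tumor-specific and
    survival-associated event counts by event type.
    """

    def __init__(
        self,
        k_max: int = 3,
        min_samples: int = 10,
        purity_min: float = 0.90,
        n_min_subpop: int = 50,
        delta_psi_min: float = 20.0,
        n_min_survival: int = 30,
        alpha: float = 0.01,
        wilcoxon_gate: bool = True,
        wilcoxon_alpha: float = 0.05,
        variance_floor: float = 1e-4,
        restarts: int = 5,
        random_state: int = 0,
    ):
        self.k_max = k_max
        self.min_samples = min_samples
        self.purity_min = purity_min
        self.n_min_subpop = n_min_subpop
        self.delta_psi_min = delta_psi_min
        self.n_min_survival = n_min_survival
        self.alpha = alpha
        self.wilcoxon_gate = wilcoxon_gate
        self.wilcoxon_alpha = wilcoxon_alpha
        self.variance_floor = variance_floor
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, psi: pd.DataFrame, samples: pd.DataFrame):
        self.fits_: Dict[str, GmmFit] = {}
        self.skipped_: List[Tuple[str, str]] = []
        subpops: List[SubpopulationResult] = []
        surv: List[SurvivalResult] = []
        for i, (event_id, row) in enumerate(psi.iterrows()):
            seed = np.random.SeedSequence([self.random_state, i]).generate_state(1)[0] % (2**31)
            try:
                fit = fit_gmm(
                    row,
                    k_max=self.k_max,
                    seed=int(seed),
                    event_id=str(event_id),
                    min_samples=self.min_samples,
                    variance_floor=self.variance_floor,
                    restarts=self.restarts,
                )
            except ValueError as exc:
                self.skipped_.append((str(event_id), str(exc)))
                continue
            self.fits_[str(event_id)] = fit
            try:
                comps = summarize_subpopulations(
                    fit,
                    samples,
                    purity_min=self.purity_min,
                    n_min=self.n_min_subpop,
                    delta_psi_min=self.delta_psi_min,
                    wilcoxon_gate=self.wilcoxon_gate,
                    wilcoxon_alpha=self.wilcoxon_alpha,
                )
            except ValueError as exc:
                self.skipped_.append((str(event_id), str(exc)))
                continue
            subpops.extend(comps)
            if any(c.tumor_specific for c in comps):
                surv.extend(
                    pairwise_survival(
                        fit, samples, min_n=self.n_min_survival, alpha=self.alpha
                    )
                )
        self.subpopulations_ = pd.DataFrame([vars(c) for c in subpops])
        self.survival_ = pd.DataFrame([vars(s) for s in surv])
        self.summary_ = self._summarize()
        return self

    def _summarize(self) -> Dict:
        ts_events = (
            sorted(
                set(
                    self.subpopulations_.loc[
                        self.subpopulations_["tumor_specific"], "event_id"
                    ]
                )
            )
            if len(self.subpopulations_)
            else []
        )
        sig_events = (
            sorted(set(self.survival_.loc[self.survival_["significant"], "event_id"]))
            if len(self.survival_)
            else []
        )
        by_type = lambda ids: dict(
            pd.Series([_event_type(e) for e in ids]).value_counts()
        ) if ids else {}
        return {
            "n_events_fitted": len(self.fits_),
            "n_events_skipped": len(self.skipped_),
            "n_tumor_specific_events": len(ts_events),
            "tumor_specific_events": ts_events,
            "tumor_specific_by_type": {k: int(v) for k, v in by_type(ts_events).items()},
            "n_survival_events": len(sig_events),
            "survival_events": sig_events,
            "survival_by_type": {k: int(v) for k, v in by_type(sig_events).items()},
        }


def stratify_cohort(
    psi: pd.DataFrame, samples: pd.DataFrame, **params
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict]:
    """Functional wrapper over :class:`GmmStratifier`."""
    model = GmmStratifier(**params).fit(psi, samples)
    return model.subpopulations_, model.survival_, model.summary_
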