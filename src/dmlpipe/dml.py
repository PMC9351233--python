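"""Per-locus differential-methylation testing.

At each united CpG locus the methylated/unmethylated counts are modeled
by a binomial logistic regression

    logit(p_i) = b0 + b1 * treatment_i + b2 * stage_i

fitted by maximum likelihood (Newton/IRLS with step-halving). Treatment
is tested by the likelihood-ratio statistic G = 2(l_full − l_reduced)
against chi-squared with 1 df, after scaling by the Pearson dispersion
estimate phi when phi > 1 (the McCullagh–Nelder-style overdispersion
correction — never deflating). The maturation-stage covariate enters as
a single ordinal term by default: eight samples cannot support a dummy
column per stage plus treatment.

False discovery is controlled by SLIM q-values: the true-null proportion
pi0 is estimated by a sliding-linear-model fit to the empirical p-value
CDF and multiplies the Benjamini–Hochberg adjusted p-values.

DML are loci with q < 0.01 (strict), |pooled percent difference| >= 50
(inclusive), and no C→T SNP overlap — exactly the published thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import chi2

from .methylation import MethylMatrix, TREATMENTS
from .snps import SnpSet

_ETA_MAX = 30.0
_MU_EPS = 1e-10


@dataclass
class LocusModelFit:
    beta: np.ndarray
    loglik_full: float
    loglik_reduced: float
    G: float
    phi: float
    p_value: float
    p_uncorrected: float
    converged: bool


@dataclass
class Pi0Estimate:
    """Estimated proportion of true-null p-values (SLIM)."""

    pi0: float
    n_bins: int
    lambda_window: float
    slopes: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 < self.pi0 <= 1.0:
            raise ValueError("pi0 must be in (0, 1]")


# ---------------------------------------------------------------------------
# Vectorized binomial-logistic ML fits
# ---------------------------------------------------------------------------

def _loglik(meth, cov, mu):
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    return (meth * np.log(mu) + (cov - meth) * np.log1p(-mu)).sum(axis=1)


def fit_binomial_glm(meth: np.ndarray, cov: np.ndarray, X: np.ndarray,
                     max_iter: int = 50, tol: float = 1e-8
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit logit(mu) = X beta at every locus simultaneously.

    ``meth``/``cov``: (loci, samples); ``X``: (samples, k) design matrix.
    Newton steps with step-halving (up to 20 halvings per step) and a
    small ridge guard against separation-singular Hessians. Returns
    (beta (loci, k), loglik (loci,), converged (loci,)).
    """
    L, S = meth.shape
    k = X.shape[1]
    frac = meth.sum(axis=1) / np.maximum(cov.sum(axis=1), 1)
    beta = np.zeros((L, k))
    beta[:, 0] = logit(np.clip(frac, 1e-3, 1 - 1e-3))
    eta = np.clip(beta @ X.T, -_ETA_MAX, _ETA_MAX)
    ll = _loglik(meth, cov, expit(eta))
    converged = np.zeros(L, dtype=bool)
    eye = np.eye(k)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        mu = expit(np.clip(beta[active] @ X.T, -_ETA_MAX, _ETA_MAX))
        mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
        w = cov[active] * mu * (1 - mu)
        grad = np.einsum("ls,sk->lk", meth[active] - cov[active] * mu, X)
        hess = np.einsum("ls,sk,sj->lkj", w, X, X) + 1e-9 * eye
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(hess + 1e-6 * eye, grad[..., None])[..., 0]
        step = np.clip(step, -10.0, 10.0)
        new_beta = beta[active] + step
        new_eta = np.clip(new_beta @ X.T, -_ETA_MAX, _ETA_MAX)
        new_ll = _loglik(meth[active], cov[active], expit(new_eta))
        # step-halve loci whose likelihood worsened
        for _h in range(20):
            worse = new_ll < ll[active] - 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
            new_beta[worse] = beta[active][worse] + step[worse]
            ne = np.clip(new_beta[worse] @ X.T, -_ETA_MAX, _ETA_MAX)
            new_ll[worse] = _loglik(meth[active][worse], cov[active][worse],
                                    expit(ne))
        improved = new_ll - ll[active]
        beta[active] = new_beta
        ll[active] = new_ll
        done = np.abs(improved) < tol
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
    return beta, ll, converged


def _design(samples: pd.DataFrame, covariate: str | None,
            categorical_covariate: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """(full, reduced) design matrices; column 1 of full is treatment."""
    treat = (samples["treatment"] == TREATMENTS[0]).to_numpy(float)
    cols = [np.ones(len(samples)), treat]
    if covariate is not None:
        v = samples[covariate].to_numpy(float)
        if categorical_covariate:
            levels = np.unique(v)[1:]
            for lev in levels:
                cols.append((v == lev).astype(float))
        else:
            cols.append(v - v.mean())
    X_full = np.column_stack(cols)
    X_red = np.delete(X_full, 1, axis=1)
    return X_full, X_red


def fit_matrix(matrix: MethylMatrix, covariate: str | None = "stage",
               categorical_covariate: bool = False) -> pd.DataFrame:
    """Likelihood-ratio treatment test at every locus of a united matrix.

    Returns a frame with chrom, pos, G, phi, p_value (overdispersion-
    corrected), p_uncorrected, meth_diff and convergence flags.
    """
    meth = matrix.meth.astype(float)
    cov = matrix.coverage.astype(float)
    X_full, X_red = _design(matrix.samples, covariate, categorical_covariate)
    k = X_full.shape[1]
    n = cov.shape[1]
    if n - k <= 0:
        raise ValueError("not enough samples for the requested model")

    beta_f, ll_f, conv_f = fit_binomial_glm(meth, cov, X_full)
    _, ll_r, conv_r = fit_binomial_glm(meth, cov, X_red)
    G = np.maximum(2.0 * (ll_f - ll_r), 0.0)

    mu = expit(np.clip(beta_f @ X_full.T, -_ETA_MAX, _ETA_MAX))
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    pearson = ((meth - cov * mu) ** 2 / (cov * mu * (1 - mu))).sum(axis=1)
    phi = pearson / (n - k)

    corrected = G / np.maximum(phi, 1.0)
    p = chi2.sf(corrected, df=1)
    p_unc = chi2.sf(G, df=1)
    converged = conv_f & conv_r
    if not converged.all():
        warnings.warn(f"{(~converged).sum()} loci failed to converge; "
                      "reported with p = 1")
        p[~converged] = 1.0
        p_unc[~converged] = 1.0

    out = matrix.loci.copy()
    out["G"] = G
    out["phi"] = phi
    out["p_value"] = p
    out["p_uncorrected"] = p_unc
    out["meth_diff"] = meth_difference(matrix)
    out["beta_treatment"] = beta_f[:, 1]
    out["converged"] = converged
    return out


def fit_locus(meth: np.ndarray, cov: np.ndarray, treatment: np.ndarray,
              covariate: np.ndarray | None = None) -> LocusModelFit:
    """Single-locus convenience wrapper around the vectorized fit."""
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(treatment))],
        "treatment": np.where(np.asarray(treatment, bool),
                              TREATMENTS[0], TREATMENTS[1]),
    })
    if covariate is not None:
        samples["stage"] = covariate
    m = MethylMatrix(pd.DataFrame({"chrom": ["x"], "pos": [1]}), samples,
                     np.asarray(meth)[None, :].astype(np.int64),
                     (np.asarray(cov) - np.asarray(meth))[None, :].astype(
                         np.int64))
    row = fit_matrix(m, covariate="stage" if covariate is not None else None
                     ).iloc[0]
    X_full, _ = _design(samples, "stage" if covariate is not None else None)
    beta_f, ll_f, _ = fit_binomial_glm(
        m.meth.astype(float), m.coverage.astype(float), X_full)
    _, ll_r, _ = fit_binomial_glm(
        m.meth.astype(float), m.coverage.astype(float),
        np.delete(X_full, 1, axis=1))
    return LocusModelFit(beta=beta_f[0], loglik_full=float(ll_f[0]),
                         loglik_reduced=float(ll_r[0]), G=float(row["G"]),
                         phi=float(row["phi"]), p_value=float(row["p_value"]),
                         p_uncorrected=float(row["p_uncorrected"]),
                         converged=bool(row["converged"]))


# ---------------------------------------------------------------------------
# Methylation difference
# ---------------------------------------------------------------------------

def meth_difference(matrix: MethylMatrix) -> np.ndarray:
    """Pooled percent difference (treatment − control) per locus.

    Counts are pooled within each group before taking proportions, i.e.
    samples contribute in proportion to their coverage.
    """
    t_mask, c_mask = matrix.treatment_masks()
    mt = matrix.meth[:, t_mask].sum(axis=1)
    ct = matrix.coverage[:, t_mask].sum(axis=1)
    mc = matrix.meth[:, c_mask].sum(axis=1)
    cc = matrix.coverage[:, c_mask].sum(axis=1)
    return 100.0 * (mt / np.maximum(ct, 1) - mc / np.maximum(cc, 1))


# ---------------------------------------------------------------------------
# SLIM q-values
# ---------------------------------------------------------------------------

def estimate_pi0_slim(p_values: np.ndarray, n_bins: int = 100,
                      lambda_window: float = 0.2,
                      stabilization_tol: float = 0.01
                      ) -> Pi0Estimate:
    """Sliding-linear-model estimate of the true-null proportion.

    The empirical p-value CDF is regressed on lambda over sliding windows
    of width ``lambda_window`` moving toward 1; under a null/alternative
    mixture the local slope decreases toward pi0 as the window leaves the
    signal-rich region. The first slope whose change between consecutive
    windows falls below ``stabilization_tol`` is taken (minimum slope as
    fallback), clipped into (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) < 100:
        warnings.warn("fewer than 100 p-values; falling back to pi0 = 1")
        return Pi0Estimate(1.0, n_bins, lambda_window, np.array([]))
    lam = np.arange(1, n_bins) / n_bins
    cdf = np.searchsorted(np.sort(p), lam, side="right") / len(p)
    w = max(2, int(round(lambda_window * n_bins)))
    starts = np.arange(0, len(lam) - w, max(1, w // 8))
    slopes = np.empty(len(starts))
    for i, s0 in enumerate(starts):
        xs, ys = lam[s0:s0 + w], cdf[s0:s0 + w]
        slopes[i] = np.polyfit(xs, ys, 1)[0]
    diffs = np.abs(np.diff(slopes))
    stable = np.flatnonzero(diffs < stabilization_tol)
    pi0 = slopes[stable[0] + 1] if len(stable) else slopes.min()
    pi0 = float(np.clip(pi0, 1.0 / len(p), 1.0))
    return Pi0Estimate(pi0, n_bins, lambda_window, slopes)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def slim_qvalues(p_values: np.ndarray, pi0: float | None = None,
                 **pi0_kwargs) -> tuple[np.ndarray, Pi0Estimate]:
    """SLIM q-values: pi0-scaled BH-adjusted p-values.

    With ``pi0`` forced to 1 this reduces exactly to Benjamini–Hochberg.
    q is monotone nondecreasing in p and clipped to [0, 1].
    """
    if pi0 is None:
        est = estimate_pi0_slim(p_values, **pi0_kwargs)
    else:
        est = Pi0Estimate(float(pi0), 0, 0.0, np.array([]))
    q = np.minimum(est.pi0 * bh_adjust(p_values), 1.0)
    return q, est


# ---------------------------------------------------------------------------
# DML calling
# ---------------------------------------------------------------------------

def call_dml(fits: pd.DataFrame, snp_set: SnpSet | None = None,
             q_threshold: float = 0.01, diff_threshold: float = 50.0,
             pi0: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Apply the q < 0.01 and |diff| >= 50 thresholds and the SNP screen.

    ``fits`` is the output of :func:`fit_matrix`. Returns the per-locus
    record table (with q-values, direction and SNP-overlap flags) and an
    accounting dict: candidates → SNP-removed → retained, hyper/hypo.
    Hypermethylated means higher percent methylation under treatment.
    """
    records = fits.copy()
    q, est = slim_qvalues(records["p_value"].to_numpy(), pi0=pi0)
    records["q_value"] = q

    if snp_set is not None and len(snp_set):
        snp = set(zip(snp_set.positions["chrom"], snp_set.positions["pos"]))
        records["snp_overlap"] = [
            (c, p) in snp or (c, p + 1) in snp
            for c, p in zip(records["chrom"], records["pos"])]
    else:
        records["snp_overlap"] = False

    candidate = ((records["q_value"] < q_threshold)
                 & (records["meth_diff"].abs() >= diff_threshold))
    is_dml = candidate & ~records["snp_overlap"]
    direction = np.full(len(records), "ns", dtype=object)
    direction[np.flatnonzero(is_dml & (records["meth_diff"] > 0))] = "hyper"
    direction[np.flatnonzero(is_dml & (records["meth_diff"] < 0))] = "hypo"
    records["direction"] = direction
    records["is_dml"] = is_dml

    accounting = dml_accounting(int(candidate.sum()),
                                int((candidate & records["snp_overlap"]).sum()))
    accounting.update({
        "hyper": int((direction == "hyper").sum()),
        "hypo": int((direction == "hypo").sum()),
        "pi0": est.pi0,
    })
    return records, accounting


def dml_accounting(candidates: int, snp_removed: int) -> dict:
    """Candidate → retained arithmetic with percentage shares."""
    retained = candidates - snp_removed
    return {
        "candidates": candidates,
        "snp_removed": snp_removed,
        "snp_removed_percent": round(100.0 * snp_removed / candidates, 1)
        if candidates else 0.0,
        "retained": retained,
    }


def direction_shares(hypo: int, hyper: int) -> dict:
    total = hypo + hyper
    return {
        "hypo_percent": round(100.0 * hypo / total, 1) if total else 0.0,
        "hyper_percent": round(100.0 * hyper / total, 1) if total else 0.0,
    }


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_dml_bed(records: pd.DataFrame, path) -> None:
    dml = records[records["is_dml"]]
    out = pd.DataFrame({"chrom": dml["chrom"], "start": dml["pos"] - 1,
                        "end": dml["pos"] + 1,
                        "name": dml["direction"],
                        "score": np.round(dml["meth_diff"], 2)})
    out.to_csv(path, sep="\t", header=False, index=False)


def write_dml_tsv(records: pd.DataFrame, path) -> None:
    cols = ["chrom", "pos", "meth_diff", "p_value", "q_value", "direction",
            "snp_overlap"]
    records[cols].to_csv(path, sep="\t", index=False)
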