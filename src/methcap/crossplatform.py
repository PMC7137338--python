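"""MBDE-vs-targeted-bisulfite concordance.

Per-CpG beta regression on bisulfite methylation proportions (logit mean
link, common per-CpG precision, Wald test of the group effect); propagation
of region-level MBD statistics to the CpGs they contain; per-CpG joint
classification (hyper/hypo/iso/other); density-stratified Pearson
correlation; and >= 1-bp DMR overlap partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, polygamma, psi, gammaln
from scipy.stats import norm, pearsonr
from sklearn.base import BaseEstimator

_ZERO_TOL = 1e-12


# ---------------------------------------------------------------------------
# beta regression, vectorized across CpGs
# ---------------------------------------------------------------------------

def _squeeze(y: np.ndarray, n: int) -> np.ndarray:
    """Pull proportions into the open unit interval: (y*(n-1) + 0.5) / n."""
    return (y * (n - 1) + 0.5) / n


def _beta_loglik(y, mu, phi):
    a = phi * mu
    b = phi * (1.0 - mu)
    return (
        gammaln(phi)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    ).sum(axis=-1)


def _beta_score_info(y, x, b0, b1, tau):
    """Score vector and expected information of (b0, b1, log phi) for every
    CpG; closed forms of the beta-regression information matrix."""
    phi = np.exp(tau)[:, None]
    eta = b0[:, None] + b1[:, None] * x
    mu = expit(eta)
    a = phi * mu
    b = phi * (1.0 - mu)
    ystar = np.log(y) - np.log1p(-y)
    mustar = psi(a) - psi(b)
    dmu = mu * (1.0 - mu)

    s_eta = phi * (ystar - mustar) * dmu
    score0 = s_eta.sum(axis=1)
    score1 = (s_eta * x).sum(axis=1)
    s_phi = (
        psi(phi) - mu * psi(a) - (1.0 - mu) * psi(b)
        + mu * np.log(y) + (1.0 - mu) * np.log1p(-y)
    )
    score_tau = (phi * s_phi).sum(axis=1)

    tg_a = polygamma(1, a)
    tg_b = polygamma(1, b)
    w = phi**2 * (tg_a + tg_b) * dmu**2
    i00 = w.sum(axis=1)
    i01 = (w * x).sum(axis=1)
    i11 = (w * x**2).sum(axis=1)
    c = phi**2 * dmu * (mu * tg_a - (1.0 - mu) * tg_b)
    i0t = c.sum(axis=1)
    i1t = (c * x).sum(axis=1)
    i_phi = (mu**2 * tg_a + (1.0 - mu) ** 2 * tg_b - polygamma(1, phi)).sum(axis=1)
    itt = np.exp(2 * tau) * i_phi

    score = np.stack([score0, score1, score_tau], axis=1)
    info = np.empty((len(b0), 3, 3))
    info[:, 0, 0] = i00
    info[:, 0, 1] = info[:, 1, 0] = i01
    info[:, 1, 1] = i11
    info[:, 0, 2] = info[:, 2, 0] = i0t
    info[:, 1, 2] = info[:, 2, 1] = i1t
    info[:, 2, 2] = itt
    return score, info, mu


def _fit_beta_regression(
    y: np.ndarray, x: np.ndarray, max_iter: int = 60, tol: float = 1e-6
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fisher-scoring fit of logit-link beta regression per CpG (rows of y).

    x is the 0/1 group indicator shared by all rows. Returns (b0, b1,
    tau, converged)."""
    n_cpg, m = y.shape
    logit = lambda p: np.log(p) - np.log1p(-p)
    mean_a = y[:, x == 0].mean(axis=1)
    mean_b = y[:, x == 1].mean(axis=1)
    clip = lambda p: np.clip(p, 1e-4, 1 - 1e-4)
    b0 = logit(clip(mean_a))
    b1 = logit(clip(mean_b)) - b0
    resid_var = np.maximum(
        np.concatenate(
            [y[:, x == 0] - mean_a[:, None], y[:, x == 1] - mean_b[:, None]], axis=1
        ).var(axis=1),
        1e-5,
    )
    mean_all = clip(y.mean(axis=1))
    tau = np.log(np.clip(mean_all * (1 - mean_all) / resid_var - 1.0, 1.0, 1e4))

    converged = np.zeros(n_cpg, dtype=bool)
    for _ in range(max_iter):
        score, info, _ = _beta_score_info(y, x, b0, b1, tau)
        # ridge the information for safety, then solve batched
        info = info + 1e-8 * np.eye(3)
        try:
            step = np.linalg.solve(info, score[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(i, s, rcond=None)[0] for i, s in zip(info, score)]
            )
        step = np.clip(step, -2.0, 2.0)
        active = ~converged
        b0[active] += step[active, 0]
        b1[active] += step[active, 1]
        tau[active] = np.clip(tau[active] + step[active, 2], -2.0, 12.0)
        newly = np.abs(step).max(axis=1) < tol
        converged |= newly
        if converged.all():
            break
    return b0, b1, tau, converged


class CpGBetaRegression(BaseEstimator):
    """Per-CpG beta regression of bisulfite methylation proportions.

    fit(X, y): X is a DataFrame with columns chrom, pos and per-sample
    (methylated, total) column pairs named ``m_<sample>``/``t_<sample>``,
    or a tuple (sites, methylated, total) of a chrom/pos frame and two
    (n_cpg, n_samples) arrays. y gives each sample's group; the contrast
    is (tumor, reference).

    Fitted attributes: ``results_`` (chrom, pos, diff, pvalue, converged,
    plus fitted group proportions) and ``skipped_`` (CpGs with < 2 covered
    samples in either group, with reasons).
    """

    def __init__(
        self,
        contrast: Tuple[str, str] = ("primary", "normal"),
        min_covered_per_group: int = 2,
        max_iter: int = 60,
        tol: float = 1e-6,
    ):
        self.contrast = contrast
        self.min_covered_per_group = min_covered_per_group
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y: Sequence[str]) -> "CpGBetaRegression":
        sites, meth, total = _coerce_counts(X)
        groups = np.asarray(list(y))
        tumor, ref = self.contrast
        use = np.isin(groups, [tumor, ref])
        meth, total, groups = meth[:, use], total[:, use], groups[use]
        x_full = (groups == tumor).astype(float)
        if x_full.sum() == 0 or (1 - x_full).sum() == 0:
            raise ValueError("both contrast groups need >= 1 sample")

        covered = total > 0
        n_ref = (covered & (x_full == 0)).sum(axis=1)
        n_tum = (covered & (x_full == 1)).sum(axis=1)
        ok = (n_ref >= self.min_covered_per_group) & (
            n_tum >= self.min_covered_per_group
        )
        self.skipped_ = sites.loc[~ok].assign(
            reason="insufficient coverage in one or both groups"
        ).reset_index(drop=True)

        sites_ok = sites.loc[ok].reset_index(drop=True)
        meth, total, cov = meth[ok], total[ok], covered[ok]
        n_cpg = len(sites_ok)
        if n_cpg == 0:
            self.results_ = sites_ok.assign(
                diff=[], pvalue=[], prop_ref=[], prop_tumor=[], converged=[]
            )
            return self

        # proportions; uncovered samples are imputed at the CpG's pooled
        # mean so they carry no group information
        with np.errstate(divide="ignore", invalid="ignore"):
            prop = np.where(cov, meth / np.maximum(total, 1), np.nan)
        pooled = np.nanmean(prop, axis=1)
        prop = np.where(np.isnan(prop), pooled[:, None], prop)
        m = prop.shape[1]
        yq = _squeeze(prop, m)

        b0, b1, tau, converged = _fit_beta_regression(
            yq, x_full, max_iter=self.max_iter, tol=self.tol
        )
        _, info, _ = _beta_score_info(yq, x_full, b0, b1, tau)
        info = info + 1e-8 * np.eye(3)
        cov_mat = np.linalg.inv(info)
        se_b1 = np.sqrt(np.maximum(cov_mat[:, 1, 1], 1e-300))
        z = b1 / se_b1
        pvalue = 2.0 * norm.sf(np.abs(z))
        pvalue = np.where(converged, pvalue, 1.0)  # conservative fallback

        # fitted means are on the squeezed scale; report proportions on the
        # original [0, 1] scale by inverting the squeeze transform
        unsqueeze = lambda mu: np.clip((mu * m - 0.5) / (m - 1), 0.0, 1.0)
        prop_ref = unsqueeze(expit(b0))
        prop_tum = unsqueeze(expit(b0 + b1))
        res = sites_ok.copy()
        res["prop_ref"] = prop_ref
        res["prop_tumor"] = prop_tum
        res["diff"] = prop_tum - prop_ref
        res["pvalue"] = pvalue
        res["converged"] = converged
        self.results_ = res
        return self


def _coerce_counts(X):
    if isinstance(X, tuple) and len(X) == 3:
        sites, meth, total = X
        return (
            sites[["chrom", "pos"]].reset_index(drop=True),
            np.asarray(meth, dtype=float),
            np.asarray(total, dtype=float),
        )
    df = X
    m_cols = [c for c in df.columns if c.startswith("m_")]
    t_cols = ["t_" + c[2:] for c in m_cols]
    return (
        df[["chrom", "pos"]].reset_index(drop=True),
        df[m_cols].to_numpy(dtype=float),
        df[t_cols].to_numpy(dtype=float),
    )


def beta_regression_per_cpg(
    counts: pd.DataFrame,
    design: Sequence[str],
    contrast: Tuple[str, str] = ("primary", "normal"),
    **params,
) -> pd.DataFrame:
    """Functional wrapper over :class:`CpGBetaRegression`."""
    model = CpGBetaRegression(contrast=contrast, **params)
    model.fit(counts, design)
    return model.results_


# ---------------------------------------------------------------------------
# propagation, classification, correlation, overlap
# ---------------------------------------------------------------------------

def propagate_region_stats(
    regions: pd.DataFrame, cpg_sites: pd.DataFrame
) -> pd.DataFrame:
    """Attach each region's logFC and combined p to the CpGs it contains.

    Nearby CpGs are frequently co-methylated, so region statistics stand in
    for site statistics wherever MBD coverage was tested. CpGs outside all
    regions are returned with mbde_covered=False. Overlapping regions are a
    contract violation and raise."""
    out = cpg_sites[["chrom", "pos"]].copy()
    out["mbde_covered"] = False
    out["mbde_logfc"] = np.nan
    out["mbde_p"] = np.nan
    out["region_id"] = -1
    for chrom, sub in regions.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping regions on {chrom}")
        mask = out["chrom"].to_numpy() == chrom
        pos = out.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
        rows = np.flatnonzero(mask)[inside]
        ridx = sub.index.to_numpy()[idx[inside]]
        out.loc[rows, "mbde_covered"] = True
        out.loc[rows, "mbde_logfc"] = regions.loc[ridx, "logFC"].to_numpy()
        out.loc[rows, "mbde_p"] = regions.loc[ridx, "simes_p"].to_numpy()
        out.loc[rows, "region_id"] = ridx
    return out


def classify_cpgs(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Joint per-CpG classification of records covered by both methods.

    Per-method calls: TE hyper/hypo by the sign of the fitted proportion
    difference (exact zero -> none); MBDE hyper/hypo when logFC has that
    sign AND p < alpha, else none. Joint: hyper-concordant, hypo-concordant,
    iso (TE difference exactly 0, MBDE logFC exactly 0 with p >= alpha) or
    other, subclassified by which method called what."""
    required = {"te_diff", "te_p", "mbde_logfc", "mbde_p"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing fields: {sorted(missing)}")
    te_diff = records["te_diff"].to_numpy(dtype=float)
    mbde_lfc = records["mbde_logfc"].to_numpy(dtype=float)
    mbde_p = records["mbde_p"].to_numpy(dtype=float)
    if np.any(np.isnan(te_diff)) or np.any(np.isnan(mbde_lfc)):
        raise ValueError("records must be covered by both methods")

    te_zero = np.abs(te_diff) < _ZERO_TOL
    te_call = np.where(te_zero, "none", np.where(te_diff > 0, "hyper", "hypo"))
    mbde_sig = mbde_p < alpha
    mbde_zero = np.abs(mbde_lfc) < _ZERO_TOL
    mbde_call = np.where(
        mbde_sig & ~mbde_zero, np.where(mbde_lfc > 0, "hyper", "hypo"), "none"
    )

    joint = np.full(len(records), "other", dtype=object)
    joint[(te_call == "hyper") & (mbde_call == "hyper")] = "hyper-concordant"
    joint[(te_call == "hypo") & (mbde_call == "hypo")] = "hypo-concordant"
    joint[te_zero & mbde_zero & ~mbde_sig] = "iso"

    sub = np.full(len(records), "none", dtype=object)
    other = joint == "other"
    sub[other & (te_call == "hyper") & (mbde_call == "none")] = "TE-only-hyper"
    sub[other & (te_call == "hypo") & (mbde_call == "none")] = "TE-only-hypo"
    sub[other & (te_call == "none") & (mbde_call == "hyper")] = "MBDE-only-hyper"
    sub[other & (te_call == "none") & (mbde_call == "hypo")] = "MBDE-only-hypo"
    sub[other & (te_call == "hyper") & (mbde_call == "hypo")] = "discordant"
    sub[other & (te_call == "hypo") & (mbde_call == "hyper")] = "discordant"

    out = records.copy()
    out["te_call"] = te_call
    out["mbde_call"] = mbde_call
    out["joint_class"] = joint
    out["joint_subclass"] = sub
    return out


@dataclass
class ConcordanceSummary:
    per_stratum: pd.DataFrame  # density_class, n, pearson_r, class counts
    overall_r: float
    n_total: int


def correlate_methods(
    records: pd.DataFrame, stratify_by_density: bool = True, min_n: int = 3
) -> ConcordanceSummary:
    """Pearson correlation between MBDE logFC and TE proportion difference,
    within each CpG-density stratum. Strata with < min_n records or zero
    variance report r = NaN (undefined), never 0."""

    def _r(sub: pd.DataFrame) -> float:
        if len(sub) < min_n:
            return float("nan")
        x = sub["mbde_logfc"].to_numpy(dtype=float)
        y = sub["te_diff"].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan")
        return float(pearsonr(x, y)[0])

    rows = []
    if stratify_by_density and "density_class" in records.columns:
        strata = records.groupby("density_class", sort=False)
    else:
        strata = [("all", records)]
    for name, sub in strata:
        counts = sub["joint_class"].value_counts() if "joint_class" in sub else {}
        rows.append(
            {
                "density_class": name,
                "n": len(sub),
                "pearson_r": _r(sub),
                "n_hyper_concordant": int(counts.get("hyper-concordant", 0)),
                "n_hypo_concordant": int(counts.get("hypo-concordant", 0)),
                "n_iso": int(counts.get("iso", 0)),
                "n_other": int(counts.get("other", 0)),
            }
        )
    return ConcordanceSummary(
        per_stratum=pd.DataFrame(rows),
        overall_r=_r(records),
        n_total=len(records),
    )


@dataclass
class OverlapPartition:
    both_a: pd.DataFrame  # a-regions sharing >= 1 bp with a same-direction b-region
    a_only: pd.DataFrame
    both_b: pd.DataFrame
    b_only: pd.DataFrame
    counts: Dict[str, Dict[str, int]] = field(default_factory=dict)


def overlap_dmrs(set_a: pd.DataFrame, set_b: pd.DataFrame) -> OverlapPartition:
    """Partition two DMR sets by >= 1-bp same-direction overlap.

    A region counts once in 'both' regardless of how many partners it
    touches. Each input set must be internally non-overlapping."""

    def _check(df: pd.DataFrame, label: str) -> None:
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            if np.any(sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]):
                raise ValueError(f"set {label} has overlapping regions on {chrom}")

    _check(set_a, "a")
    _check(set_b, "b")

    def _hits(query: pd.DataFrame, target: pd.DataFrame) -> np.ndarray:
        flags = np.zeros(len(query), dtype=bool)
        for direction in ("hyper", "hypo"):
            q = query["direction"] == direction
            t = target[target["direction"] == direction]
            for chrom, tsub in t.groupby("chrom", sort=False):
                tsub = tsub.sort_values("start")
                ts = tsub["start"].to_numpy()
                te = np.maximum.accumulate(tsub["end"].to_numpy())
                mask = q & (query["chrom"] == chrom)
                qs = query.loc[mask, "start"].to_numpy()
                qe = query.loc[mask, "end"].to_numpy()
                idx = np.searchsorted(ts, qe, side="left") - 1
                hit = (idx >= 0) & (te[np.maximum(idx, 0)] > qs)
                flags[np.flatnonzero(mask.to_numpy())] |= hit
        return flags

    a_hit = _hits(set_a, set_b)
    b_hit = _hits(set_b, set_a)

    def _dir_counts(df, mask):
        sub = df.loc[mask]
        return {
            "hyper": int((sub["direction"] == "hyper").sum()),
            "hypo": int((sub["direction"] == "hypo").sum()),
        }

    counts = {
        "both_a": _dir_counts(set_a, a_hit),
        "a_only": _dir_counts(set_a, ~a_hit),
        "both_b": _dir_counts(set_b, b_hit),
        "b_only": _dir_counts(set_b, ~b_hit),
    }
    return OverlapPartition(
        both_a=set_a.loc[a_hit].reset_index(drop=True),
        a_only=set_a.loc[~a_hit].reset_index(drop=True),
        both_b=set_b.loc[b_hit].reset_index(drop=True),
        b_only=set_b.loc[~b_hit].reset_index(drop=True),
        counts=counts,
    )
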