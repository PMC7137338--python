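"""End-to-end DMR calling as a scikit-learn style estimator."""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from methcap.mbd_dmr.counting import WindowCountMatrix, count_windows, filter_windows
from methcap.mbd_dmr.glm import estimate_dispersion, fit_nb_glm, _group_codes
from methcap.mbd_dmr.normalization import estimate_normalization
from methcap.mbd_dmr.regions import build_regions
from methcap.simdata.capture import FragmentSet


class DMRCaller(BaseEstimator):
    """Windowed differential-binding caller for MBD-capture coverage.

    fit(X, y) accepts either a list of per-sample :class:`FragmentSet`
    (with ``chrom_sizes``) or a prebuilt :class:`WindowCountMatrix`; ``y``
    gives group labels per sample (defaults to the matrix's sample sheet).

    Fitted attributes
    -----------------
    matrix_ : filtered, normalized WindowCountMatrix
    window_results_ : per-window logFC and p-value for the contrast
    regions_ : region table with Simes p, BH FDR, direction, significance
    dmrs_ : the significant subset of ``regions_``
    """

    def __init__(
        self,
        contrast: Tuple[str, str] = ("primary", "normal"),
        width: int = 200,
        step: int = 10,
        fragment_extension: Optional[int] = 200,
        min_count_sum: int = 30,
        min_avg_logcpm: float = -1.0,
        excluded_chroms: Tuple[str, ...] = ("X", "Y"),
        max_gap: int = 50,
        fdr_cutoff: float = 0.05,
        norm: str = "tmm",
        norm_bin_width: int = 10_000,
        prior_df: float = 10.0,
    ):
        self.contrast = contrast
        self.width = width
        self.step = step
        self.fragment_extension = fragment_extension
        self.min_count_sum = min_count_sum
        self.min_avg_logcpm = min_avg_logcpm
        self.excluded_chroms = excluded_chroms
        self.max_gap = max_gap
        self.fdr_cutoff = fdr_cutoff
        self.norm = norm
        self.norm_bin_width = norm_bin_width
        self.prior_df = prior_df

    def fit(
        self,
        X: Union[Sequence[FragmentSet], WindowCountMatrix],
        y: Optional[Sequence[str]] = None,
        chrom_sizes: Optional[Dict[str, int]] = None,
        dispersion: Optional[np.ndarray] = None,
    ) -> "DMRCaller":
        if isinstance(X, WindowCountMatrix):
            matrix = X
            fragment_sets = None
        else:
            if chrom_sizes is None:
                raise ValueError("chrom_sizes is required when X is fragment sets")
            fragment_sets = list(X)
            matrix = count_windows(
                fragment_sets,
                chrom_sizes,
                width=self.width,
                step=self.step,
                fragment_extension=self.fragment_extension,
                groups=y,
            )
        if y is not None:
            matrix.samples["group"] = list(y)

        if self.norm == "tmm" and matrix.norm_factors is None:
            factors = estimate_normalization(
                matrix,
                bin_width=self.norm_bin_width,
                fragment_sets=fragment_sets,
                chrom_sizes=chrom_sizes,
            )
            matrix = matrix.with_factors(factors)
        elif self.norm == "totals":
            matrix = matrix.with_factors(np.ones(matrix.n_samples))

        matrix = filter_windows(
            matrix,
            min_count_sum=self.min_count_sum,
            min_avg_logcpm=self.min_avg_logcpm,
            excluded_chroms=self.excluded_chroms,
        )
        self.matrix_ = matrix
        self.window_results_ = fit_nb_glm(
            matrix,
            contrast=self.contrast,
            prior_df=self.prior_df,
            dispersion=dispersion,
        )
        groups_arr = np.asarray(list(matrix.samples["group"]))
        self.regions_ = build_regions(
            self.window_results_,
            max_gap=self.max_gap,
            fdr_cutoff=self.fdr_cutoff,
            counts=matrix.counts,
            group_mask_a=groups_arr == self.contrast[0],
            group_mask_b=groups_arr == self.contrast[1],
            eff_lib_sizes=matrix.effective_lib_sizes(),
        )
        self.dmrs_ = self.regions_[self.regions_["significant"]].reset_index(drop=True)
        return self

    def estimate_shared_dispersion(self) -> np.ndarray:
        """Dispersion from the fitted matrix's full group layout; lets
        several contrasts reuse one estimate."""
        matrix = self.matrix_
        codes, labels = _group_codes(list(matrix.samples["group"]))
        return estimate_dispersion(
            matrix.counts.astype(float),
            matrix.effective_lib_sizes(),
            codes,
            len(labels),
            prior_df=self.prior_df,
        )


def call_dmrs(
    X,
    design: Optional[Sequence[str]] = None,
    contrast: Tuple[str, str] = ("primary", "normal"),
    fdr_cutoff: float = 0.05,
    chrom_sizes: Optional[Dict[str, int]] = None,
    **params,
) -> pd.DataFrame:
    """Functional wrapper over :class:`DMRCaller`; returns the region table
    (all regions, with a ``significant`` flag)."""
    caller = DMRCaller(contrast=contrast, fdr_cutoff=fdr_cutoff, **params)
    caller.fit(X, y=design, chrom_sizes=chrom_sizes)
    return caller.regions_
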