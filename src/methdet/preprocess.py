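"""Spot QC, ratio summarization, normalization and methylation calls.

The filtering chain follows the assay's published processing rules:

1. Background per channel and subarray is the mean foreground of the empty
   spots; it is subtracted from every spot and floored at a small epsilon.
2. A spot is *informative* only if it is unflagged and both channels'
   background-subtracted signals are at least ``control_multiplier`` (2 by
   default) times the slide-level mean of the hybridization-control spots
   for that channel (the nonspecific-binding floor).
3. A gene needs at least ``min_informative_spots`` (2 of its 3 replicate
   spots) to be measured in a sample; its value is the mean over informative
   spots of the ratio R = control / test.
4. Per sample, M = log2(R) is lowess-normalized against spot intensity and
   the fit subtracted. The intensity covariate is the *control-channel*
   (mock-digested, template-only) log2 signal: in this assay the test
   channel's intensity is itself the methylation signal, so the
   conventional two-channel mean intensity is deterministically coupled to
   M and regressing on it would remove the biology along with the bias.
5. Genes missing in strictly more than ``max_missing_frac`` (25 %) of the
   samples are dropped.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .arrays import SampleArray
from .layout import SpotRole

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"


class ProcessingError(RuntimeError):
    """Raised when a slide cannot be processed (e.g. no usable control spots)."""


@dataclass
class MethylationMatrix:
    """Gene x sample normalized log2 methylation ratios.

    ``values`` holds M = log2(control/test) with NaN for missing entries;
    ``calls`` (optional) the binary methylated/unmethylated categorization;
    ``diagnostics`` per-sample pre/post-normalization M-vs-A tables.
    """

    values: pd.DataFrame
    calls: Optional[pd.DataFrame] = None
    diagnostics: Dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def to_tsv(self, path: Path | str) -> None:
        self.values.rename_axis("gene_id").to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: Path | str) -> "MethylationMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(values=values)


def preprocess_sample(
    array: SampleArray,
    control_multiplier: float = 2.0,
    min_informative_spots: int = 2,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Summarize one slide into per-gene ratios.

    Returns a DataFrame indexed by gene with columns ``ratio`` (mean over
    informative spots of R = control/test, NaN if the gene has fewer than
    ``min_informative_spots`` informative spots), ``a_value`` (mean
    control-channel log2 intensity, the covariate of the normalization fit)
    and ``n_informative``.
    """
    array.validate()
    spots = array.spots
    sub = np.array([s.subarray for s in spots])
    fg_c = np.array([s.fg_control for s in spots])
    fg_t = np.array([s.fg_test for s in spots])
    ok = np.array([s.ok for s in spots])
    role = np.array([s.role.value for s in spots])

    is_empty = (role == SpotRole.EMPTY.value) & ok
    if not is_empty.any():
        raise ProcessingError(
            f"{array.sample_id}: no usable empty spots to estimate background"
        )
    n_sub = array.layout.n_subarrays
    net_c = np.empty_like(fg_c)
    net_t = np.empty_like(fg_t)
    slide_bg_c = fg_c[is_empty].mean()
    slide_bg_t = fg_t[is_empty].mean()
    for k in range(n_sub):
        in_sub = sub == k
        emp = is_empty & in_sub
        # fall back to the slide-level background if a subarray lost all of
        # its empty spots to dropout
        bg_c = fg_c[emp].mean() if emp.any() else slide_bg_c
        bg_t = fg_t[emp].mean() if emp.any() else slide_bg_t
        net_c[in_sub] = np.maximum(fg_c[in_sub] - bg_c, eps)
        net_t[in_sub] = np.maximum(fg_t[in_sub] - bg_t, eps)

    is_hyb = (role == SpotRole.HYB.value) & ok
    if not is_hyb.any():
        raise ProcessingError(
            f"{array.sample_id}: no usable hybridization-control spots"
        )
    thr_c = control_multiplier * net_c[is_hyb].mean()
    thr_t = control_multiplier * net_t[is_hyb].mean()
    informative = ok & (net_c >= thr_c) & (net_t >= thr_t)

    genes = array.layout.genes
    gene_idx = {g: i for i, g in enumerate(genes)}
    ratio_sum = np.zeros(len(genes))
    a_sum = np.zeros(len(genes))
    counts = np.zeros(len(genes), dtype=int)
    for i, s in enumerate(spots):
        if s.role is SpotRole.GENE and informative[i]:
            gi = gene_idx[s.gene_id]
            counts[gi] += 1
            ratio_sum[gi] += net_c[i] / net_t[i]
            a_sum[gi] += np.log2(net_c[i])

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(counts >= min_informative_spots, ratio_sum / counts, np.nan)
        a_val = np.where(counts >= min_informative_spots, a_sum / counts, np.nan)
    return pd.DataFrame(
        {"ratio": ratio, "a_value": a_val, "n_informative": counts},
        index=pd.Index(genes, name="gene_id"),
    )


def _normalize_sample(
    m: np.ndarray, a: np.ndarray, frac: float, it: int
) -> np.ndarray:
    """Subtract the lowess fit of M on A (intensity-dependent dye bias)."""
    obs = ~np.isnan(m)
    if obs.sum() < 8:
        # too few points for a stable local fit: remove the median offset
        warnings.warn("fewer than 8 observed genes; median-centering instead of lowess")
        return m - np.nanmedian(m)
    fitted = sm_lowess(
        m[obs], a[obs], frac=frac, it=it, return_sorted=False
    )
    out = m.copy()
    out[obs] = m[obs] - fitted
    return out


def build_matrix(
    summaries: Mapping[str, pd.DataFrame],
    max_missing_frac: float = 0.25,
    normalize: bool = True,
    lowess_frac: float = 0.4,
    lowess_iterations: int = 3,
) -> MethylationMatrix:
    """Assemble the analysis matrix from per-sample gene summaries.

    Ratios are log2-transformed and (optionally) lowess-normalized against
    intensity per sample. Genes missing in strictly more than
    ``max_missing_frac`` of the retained samples are dropped; samples with no
    measured gene are excluded with a warning.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 samples to build a matrix")
    columns: Dict[str, np.ndarray] = {}
    diagnostics: Dict[str, pd.DataFrame] = {}
    genes = None
    for sid, summ in summaries.items():
        if genes is None:
            genes = list(summ.index)
        elif list(summ.index) != genes:
            raise ValueError("per-sample summaries cover different gene sets")
        m_raw = np.log2(summ["ratio"].to_numpy())
        a = summ["a_value"].to_numpy()
        if np.isnan(m_raw).all():
            warnings.warn(f"sample {sid}: all genes missing; sample excluded")
            continue
        if normalize:
            m = _normalize_sample(m_raw, a, lowess_frac, lowess_iterations)
        else:
            m = m_raw
        columns[sid] = m
        diagnostics[sid] = pd.DataFrame(
            {"a_value": a, "m_raw": m_raw, "m_normalized": m},
            index=pd.Index(genes, name="gene_id"),
        )
    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    missing_frac = values.isna().mean(axis=1)
    values = values.loc[missing_frac <= max_missing_frac]
    return MethylationMatrix(values=values, diagnostics=diagnostics)


def categorize_calls(
    matrix: MethylationMatrix, threshold_log2: float = 1.0
) -> MethylationMatrix:
    """Binary methylation calls from normalized log2 ratios.

    Under the digestion model the test channel retains signal where the
    template is methylated, so low M = log2(control/test) means methylated:
    entries at or below ``-threshold_log2`` are called methylated, at or
    above ``+threshold_log2`` unmethylated, and values inside the band take
    the nearer category (exact zero is called unmethylated). Missing entries
    stay missing.
    """
    v = matrix.values
    calls = pd.DataFrame(
        np.where(
            v.isna(),
            None,
            np.where(
                v <= -threshold_log2,
                METHYLATED,
                np.where(
                    v >= threshold_log2,
                    UNMETHYLATED,
                    np.where(v < 0, METHYLATED, UNMETHYLATED),
                ),
            ),
        ),
        index=v.index,
        columns=v.columns,
    )
    return MethylationMatrix(
        values=v, calls=calls, diagnostics=matrix.diagnostics
    )


def impute_median(values: pd.DataFrame) -> pd.DataFrame:
    """Fill missing entries with the per-gene median (for consumers that
    require a complete matrix; clustering keeps the missing mask instead)."""
    if values.isna().all(axis=1).any():
        bad = values.index[values.isna().all(axis=1)].tolist()
        raise ValueError(f"genes with no observed value cannot be imputed: {bad}")
    medians = values.median(axis=1)
    return values.apply(lambda col: col.fillna(medians))
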