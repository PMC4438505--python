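"""Synthetic cohorts of two-channel restriction-digest methylation arrays.

The generator emulates the study design: each patient's genomic DNA is
split, one aliquot digested with the methylation-sensitive enzyme Hin6I and
one mock-digested; both are amplified, labeled (test = Cy3, control = Cy5)
and competitively hybridized to the 56-gene CpG-island array. Methylation
protects a template from digestion, so the test-channel signal of a gene is
proportional to its methylated fraction while the control channel always
sees the full template. The analysis variable is the log2 ratio
M = log2(control / test); larger M means less methylation.

Ground-truth effects are specified on the M scale: per gene, the relapse
group's mean M is shifted by ``direction * log2_mean_diff`` relative to the
control group, so that the expected group fold change equals the specified
value exactly on the latent (pre-noise) values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from .arrays import FLAG_DROPOUT, FLAG_OK, SampleArray, SpotRecord, write_gpr
from .layout import ArrayLayout, SpotRole, default_layout
from .tables import (
    N_CONTROL,
    N_RELAPSE,
    PANEL_SD_CONTROL,
    PANEL_SD_RELAPSE,
    TABLE1_SCREEN,
)

RELAPSE = "relapse"
CONTROL = "control"


@dataclass(frozen=True)
class GeneEffect:
    """Between-group methylation shift of one gene probe.

    ``log2_mean_diff`` is the absolute difference of the group means of
    M = log2(control/test); ``direction`` (+1/-1) is the sign of the shift
    in the relapse group. The published screen reports absolute fold changes
    only, so directions default to +1 (relapse shifted toward higher M,
    i.e. hypomethylation) and are configurable.
    """

    gene_id: str
    log2_mean_diff: float
    direction: int = 1
    sd_relapse: float = PANEL_SD_RELAPSE
    sd_control: float = PANEL_SD_CONTROL
    panel: bool = False

    def __post_init__(self) -> None:
        if self.log2_mean_diff < 0:
            raise ValueError("log2_mean_diff must be >= 0 (direction carries sign)")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.sd_relapse <= 0 or self.sd_control <= 0:
            raise ValueError("within-group standard deviations must be positive")

    @property
    def fc_abs(self) -> float:
        return 2.0 ** self.log2_mean_diff


def default_effect_table(
    sd_relapse: float = PANEL_SD_RELAPSE,
    sd_control: float = PANEL_SD_CONTROL,
    direction: int = 1,
) -> List[GeneEffect]:
    """The 21 screened genes at their published absolute fold changes.

    The seven prognostic-panel genes are flagged. Within-group standard
    deviations default to the published panel-level values (only those are
    reported); directions are not published and default to +1.
    """
    return [
        GeneEffect(
            gene_id=gene,
            log2_mean_diff=math.log2(fc),
            direction=direction,
            sd_relapse=sd_relapse,
            sd_control=sd_control,
            panel=panel,
        )
        for gene, _p, fc, panel in TABLE1_SCREEN
    ]


def panel_effect_table(
    sd_relapse: float = PANEL_SD_RELAPSE,
    sd_control: float = PANEL_SD_CONTROL,
) -> List[GeneEffect]:
    """Only the seven prognostic-panel genes, at their published fold changes."""
    return [e for e in default_effect_table(sd_relapse, sd_control) if e.panel]


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the study: 123 patients (19 relapse / 104 non-relapse)
    profiled on the 56-probe layout, with the 21 screened genes planted at
    their published fold changes and the remaining probes carrying no group
    effect.
    """

    n_relapse: int = N_RELAPSE
    n_control: int = N_CONTROL
    effects: List[GeneEffect] = field(default_factory=default_effect_table)
    n_null_genes: Optional[int] = None  # None: fill the 56-probe layout
    null_sd: float = 1.0
    baseline_methylation: float = 0.5
    noise: float = 0.1  # spot-level multiplicative coefficient of variation
    background_mean: float = 150.0
    background_sd: float = 30.0
    dropout_rate: float = 0.02
    template_scale: float = 50000.0  # control-channel signal of a full template
    hyb_control_level: float = 200.0  # nonspecific-binding signal level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_relapse < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 samples")
        if not 0.0 < self.baseline_methylation < 1.0:
            raise ValueError("baseline_methylation must be in (0, 1)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.noise < 0 or self.background_sd < 0 or self.background_mean < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.null_sd <= 0:
            raise ValueError("null_sd must be positive")

    def gene_ids(self) -> List[str]:
        informative = [e.gene_id for e in self.effects]
        n_null = self.n_null_genes
        if n_null is None:
            n_null = max(0, 56 - len(informative))
        total = len(informative) + n_null
        if total > 56:
            raise ValueError(
                f"{total} gene probes exceed the 56-probe default layout"
            )
        nulls = [f"PROBE{i:02d}" for i in range(len(informative) + 1, total + 1)]
        return informative + nulls


@dataclass
class SimulatedCohort:
    """Arrays, labels and ground truth of one simulated cohort."""

    labels: pd.Series  # sample_id -> {"relapse", "control"}
    arrays: Dict[str, SampleArray]
    truth: Dict[str, GeneEffect]
    latent: pd.DataFrame  # gene x sample latent M (pre-noise)
    layout: ArrayLayout
    config: CohortConfig

    def __post_init__(self) -> None:
        if set(self.labels.index) != set(self.arrays):
            raise ValueError("every labeled sample needs exactly one array")
        if set(self.latent.index) != set(self.truth):
            raise ValueError("ground truth must cover every gene probe")


def simulate_sample_array(
    sample_truth: Mapping[str, float],
    layout: ArrayLayout,
    rng: np.random.Generator,
    *,
    sample_id: str = "sample",
    noise: float = 0.1,
    background_mean: float = 150.0,
    background_sd: float = 30.0,
    dropout_rate: float = 0.02,
    template_scale: float = 50000.0,
    hyb_control_level: float = 200.0,
) -> SampleArray:
    """Simulate one slide given the sample's latent per-gene log2 ratios.

    The mock-digested control channel carries the full template signal; the
    digested test channel carries ``2**(-M)`` of it (the digestion-protected,
    i.e. methylated, fraction). The three subarrays share the latent value of
    each gene but receive independent multiplicative spot noise. Positive
    controls carry full signal in both channels, hybridization controls only
    the nonspecific-binding level, empty spots only background.
    """
    sigma = math.sqrt(math.log1p(noise**2)) if noise > 0 else 0.0

    def noisy(value: float) -> float:
        if value <= 0:
            return 0.0
        if sigma == 0.0:
            return value
        return value * rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma)

    def bg() -> float:
        if background_mean == 0.0 and background_sd == 0.0:
            return 0.0
        return max(0.0, rng.normal(background_mean, background_sd))

    spots: List[SpotRecord] = []
    for sub, row, col, role, gene in layout.iter_spots():
        if role is SpotRole.GENE:
            m = sample_truth[gene]
            sig_control = template_scale
            sig_test = template_scale * 2.0 ** (-m)
        elif role is SpotRole.POSITIVE:
            sig_control = sig_test = template_scale
        elif role is SpotRole.HYB:
            sig_control = sig_test = hyb_control_level
        else:  # empty
            sig_control = sig_test = 0.0
        flag = FLAG_DROPOUT if rng.random() < dropout_rate else FLAG_OK
        spots.append(
            SpotRecord(
                subarray=sub,
                row=row,
                col=col,
                role=role,
                gene_id=gene,
                fg_test=noisy(sig_test) + bg(),
                bg_test=bg(),
                fg_control=noisy(sig_control) + bg(),
                bg_control=bg(),
                flag=flag,
            )
        )
    return SampleArray(sample_id=sample_id, layout=layout, spots=spots)


def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a labeled cohort of simulated arrays with known ground truth.

    Deterministic given ``config.seed``. Per gene, latent M values are drawn
    normally around group means that differ by exactly
    ``direction * log2_mean_diff`` (zero for null probes), then turned into
    spot intensities by :func:`simulate_sample_array`.
    """
    genes = config.gene_ids()
    layout = default_layout(tuple(genes))
    rng = np.random.default_rng(config.seed)

    sample_ids = [f"R{i + 1:02d}" for i in range(config.n_relapse)] + [
        f"C{i + 1:03d}" for i in range(config.n_control)
    ]
    labels = pd.Series(
        [RELAPSE] * config.n_relapse + [CONTROL] * config.n_control,
        index=sample_ids,
        name="label",
    )

    truth: Dict[str, GeneEffect] = {e.gene_id: e for e in config.effects}
    for g in genes:
        if g not in truth:
            truth[g] = GeneEffect(
                gene_id=g,
                log2_mean_diff=0.0,
                direction=1,
                sd_relapse=config.null_sd,
                sd_control=config.null_sd,
            )

    mu0 = -math.log2(config.baseline_methylation)
    latent = np.empty((len(genes), len(sample_ids)))
    is_relapse = (labels == RELAPSE).to_numpy()
    for gi, g in enumerate(genes):
        eff = truth[g]
        mean_r = mu0 + eff.direction * eff.log2_mean_diff
        latent[gi, is_relapse] = rng.normal(
            mean_r, eff.sd_relapse, size=config.n_relapse
        )
        latent[gi, ~is_relapse] = rng.normal(
            mu0, eff.sd_control, size=config.n_control
        )
    latent_df = pd.DataFrame(latent, index=genes, columns=sample_ids)

    arrays = {
        sid: simulate_sample_array(
            latent_df[sid],
            layout,
            rng,
            sample_id=sid,
            noise=config.noise,
            background_mean=config.background_mean,
            background_sd=config.background_sd,
            dropout_rate=config.dropout_rate,
            template_scale=config.template_scale,
            hyb_control_level=config.hyb_control_level,
        )
        for sid in sample_ids
    }
    return SimulatedCohort(
        labels=labels,
        arrays=arrays,
        truth=truth,
        latent=latent_df,
        layout=layout,
        config=config,
    )


def write_cohort(cohort: SimulatedCohort, outdir: Path | str) -> Path:
    """Write one GPR file per sample plus label and ground-truth tables."""
    outdir = Path(outdir)
    arr_dir = outdir / "arrays"
    arr_dir.mkdir(parents=True, exist_ok=True)
    for sid, array in cohort.arrays.items():
        write_gpr(array, arr_dir / f"{sid}.gpr")
    cohort.labels.rename_axis("sample_id").to_csv(outdir / "labels.tsv", sep="\t")
    truth = pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "log2_mean_diff": e.log2_mean_diff,
                "direction": e.direction,
                "sd_relapse": e.sd_relapse,
                "sd_control": e.sd_control,
                "panel": e.panel,
            }
            for e in cohort.truth.values()
        ]
    ).set_index("gene_id")
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    return outdir


def read_labels(path: Path | str) -> pd.Series:
    """Read the two-column (sample_id, label) table written by write_cohort."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = df.iloc[:, 0].astype(str)
    bad = set(labels.unique()) - {RELAPSE, CONTROL}
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected relapse/control")
    return labels


def matched_subset(cohort: SimulatedCohort, seed: int = 0) -> pd.Series:
    """Labels of a matched case-control subset (all relapse cases plus an
    equal-sized random draw of non-relapse controls)."""
    rng = np.random.default_rng(seed)
    relapse = cohort.labels[cohort.labels == RELAPSE]
    control = cohort.labels[cohort.labels == CONTROL]
    take = min(len(relapse), len(control))
    chosen = rng.choice(control.index.to_numpy(), size=take, replace=False)
    return pd.concat([relapse, control.loc[sorted(chosen)]])
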