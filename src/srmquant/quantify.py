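"""Relative quantification and detection-level statistics.

The normalization chain is: summed transition peak areas → ratio of the
endogenous (light) signal to the spiked heavy internal standard → ratio
to the mitochondrial reference protein (loading control) → percent of
the mean in healthy-control runs.

Detection level: for each protein's quantifier peptide, background
values from the control runs define a one-sided 95% bound,
mean + 1.645·SD.  Measurements whose summed light area falls below it
are reported "n.d." (not detected).

Transcript-level relative expression via the comparative-Ct method
(fold change = 2^-ΔΔCt) is included so protein and mRNA levels can be
compared on the same samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay_design import AssayPanel, PeptideAssay
from .errors import (
    InsufficientBackgroundError,
    InvalidInputError,
    ReferenceFailureError,
    StandardFailureError,
)
from . import srm_signal
from .srm_signal import ChromatogramTrace, PeakResult

LOD_Z = 1.645  # one-sided 95% normal quantile


# ---------------------------------------------------------------------------
# elementary operations

def sum_transition_areas(peak_results: Sequence[PeakResult]) -> float:
    """Sum of background-subtracted transition areas for one peptide."""
    if not peak_results:
        raise InvalidInputError("need at least one peak result")
    return float(sum(r.area for r in peak_results))


def ratio_to_standard(light_sum: float, heavy_sum: float) -> float:
    """Endogenous / heavy-standard summed-area ratio."""
    if heavy_sum <= 0:
        raise StandardFailureError(
            f"heavy-standard summed area must be positive, got {heavy_sum}"
        )
    return light_sum / heavy_sum


def normalize_to_reference(protein_ratio: float, reference_ratio: float) -> float:
    """Correct for loading by dividing by the reference protein's ratio."""
    if reference_ratio <= 0:
        raise ReferenceFailureError(
            f"reference ratio must be positive, got {reference_ratio}"
        )
    return protein_ratio / reference_ratio


def percent_of_controls(
    patient_value: float, control_values: Sequence[float]
) -> float:
    """100 x patient value / arithmetic mean of control values."""
    if len(control_values) < 2:
        raise InvalidInputError("need at least 2 control values")
    if any(v <= 0 for v in control_values):
        raise InvalidInputError("control values must all be positive")
    return 100.0 * patient_value / float(np.mean(control_values))


@dataclass(frozen=True)
class BackgroundModel:
    """Background statistics and detection level for one peptide.

    detection_level = mean + z·SD (sample SD, n−1 denominator); with
    z = 1.645 this is the one-sided 95% bound on blank signal.
    detection_level_percent expresses it relative to the mean control
    signal for the same peptide, when that signal is supplied.
    """

    peptide_sequence: str
    background_values: tuple[float, ...]
    mean: float
    sd: float
    detection_level: float
    detection_level_percent: float | None = None

    @property
    def n(self) -> int:
        return len(self.background_values)


def compute_detection_level(
    background_values: Sequence[float],
    peptide_sequence: str = "",
    mean_control_signal: float | None = None,
    z: float = LOD_Z,
) -> BackgroundModel:
    """Background model from replicate blank/background measurements."""
    values = tuple(float(v) for v in background_values)
    if len(values) < 3:
        raise InsufficientBackgroundError(
            f"need >= 3 background values, got {len(values)}"
        )
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    level = mean + z * sd
    percent = None
    if mean_control_signal is not None and mean_control_signal > 0:
        percent = 100.0 * level / mean_control_signal
    return BackgroundModel(
        peptide_sequence=peptide_sequence,
        background_values=values,
        mean=mean,
        sd=sd,
        detection_level=level,
        detection_level_percent=percent,
    )


def call_detection(summed_area: float, model: BackgroundModel) -> str:
    """'n.d.' iff the summed light area is below the detection level."""
    return "n.d." if summed_area < model.detection_level else "detected"


def reference_stability_check(
    reference_ratios: Sequence[float], cv_threshold: float = 0.20
) -> tuple[bool, float]:
    """Coefficient of variation of the reference ratio across samples.

    Pass iff CV <= threshold (default 20%): the loading control should
    not vary with disease status.
    """
    if len(reference_ratios) < 3:
        raise InvalidInputError("need >= 3 samples for a stability check")
    arr = np.asarray(reference_ratios, dtype=float)
    mean = float(np.mean(arr))
    if mean == 0:
        raise InvalidInputError("mean reference ratio is zero")
    cv = float(np.std(arr, ddof=1) / mean)
    return cv <= cv_threshold, cv


def fold_change_ddct(
    ct_target_patient: float,
    ct_hk_patient: float,
    ct_target_control: float,
    ct_hk_control: float,
) -> float:
    """Comparative-Ct fold change: 2^-ΔΔCt.

    ΔCt = Ct(target) − Ct(housekeeping); ΔΔCt = ΔCt(patient) − ΔCt(control).
    """
    for v in (ct_target_patient, ct_hk_patient, ct_target_control, ct_hk_control):
        if not math.isfinite(v):
            raise InvalidInputError("Ct values must be finite")
    ddct = (ct_target_patient - ct_hk_patient) - (ct_target_control - ct_hk_control)
    return 2.0 ** (-ddct)


@dataclass(frozen=True)
class TranscriptMeasurement:
    """One gene's qPCR result relative to a housekeeping gene and controls."""

    gene_id: str
    ct_target: float
    ct_housekeeping: float
    delta_ct_control: float

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_housekeeping

    @property
    def delta_delta_ct(self) -> float:
        return self.delta_ct - self.delta_ct_control

    @property
    def fold_change(self) -> float:
        return 2.0 ** (-self.delta_delta_ct)


# ---------------------------------------------------------------------------
# cohort-level orchestration

@dataclass(frozen=True)
class QuantConfig:
    """Signal and quantification parameters for a cohort run."""

    rt_tol: float = 0.2            # light/heavy co-elution tolerance (min)
    detect_k: float = 3.0          # apex acceptance: k noise SDs over baseline
    smooth_width: int = 5
    bounds_frac: float = 0.05      # heavy-peak boundary threshold (of apex)
    lod_z: float = LOD_Z
    cv_threshold: float = 0.20


@dataclass
class PeptideQuant:
    """Per-sample quantification of one peptide."""

    sample_id: str
    protein_id: str
    peptide_sequence: str
    light_area: float
    heavy_area: float
    ratio_to_standard: float
    light_background: float
    light_detected: bool
    coelution_pass: bool | None
    coelution_max_dev: float | None
    rank_similarity: float | None


@dataclass
class CohortResult:
    """Everything the quantification stage produces for one cohort."""

    peptide_quants: pd.DataFrame
    protein_ratios: pd.DataFrame          # sample x protein ratio_to_reference
    background_models: dict[str, BackgroundModel]   # per protein (quantifier)
    report: pd.DataFrame                  # Table-style percent / "n.d."
    report_numeric: pd.DataFrame          # percent incl. sub-LOD estimates
    detection_levels: pd.DataFrame
    qc: pd.DataFrame
    reference_cv: float
    reference_stable: bool


def _traces_for(
    run: pd.DataFrame, assay: PeptideAssay, is_heavy: bool
) -> dict[str, ChromatogramTrace]:
    sub = run[
        (run["protein_id"] == assay.protein_id)
        & (run["peptide_sequence"] == assay.peptide_sequence)
        & (run["is_heavy"] == int(is_heavy))
    ]
    traces = {}
    transitions = assay.heavy if is_heavy else assay.light
    for t in transitions:
        rows = sub[sub["fragment_label"] == t.fragment_label]
        if rows.empty:
            continue
        rows = rows.sort_values("rt_min")
        traces[t.fragment_label] = ChromatogramTrace(
            times=rows["rt_min"].to_numpy(),
            intensities=rows["intensity"].to_numpy(),
            meta={
                "sample_id": rows["sample_id"].iloc[0],
                "protein_id": assay.protein_id,
                "peptide_sequence": assay.peptide_sequence,
                "is_heavy": is_heavy,
                "fragment_label": t.fragment_label,
            },
        )
    return traces


def quantify_peptide(
    run: pd.DataFrame,
    assay: PeptideAssay,
    sample_id: str,
    config: QuantConfig = QuantConfig(),
) -> PeptideQuant:
    """Quantify one peptide in one run.

    Heavy traces anchor apex and boundaries; light and heavy are
    integrated over the same window; co-elution and transition-ranking
    QC run when the light peptide is detectable.
    """
    heavy_traces = _traces_for(run, assay, is_heavy=True)
    light_traces = _traces_for(run, assay, is_heavy=False)
    if not heavy_traces:
        raise StandardFailureError(
            f"no heavy-standard traces for peptide {assay.peptide_sequence!r} "
            f"in sample {sample_id!r}"
        )
    light_results: list[PeakResult] = []
    heavy_results: list[PeakResult] = []
    light_apexes: list[float] = []
    heavy_apexes: list[float] = []
    n_light_detected = 0
    for label, htrace in heavy_traces.items():
        window = (float(htrace.times[0]), float(htrace.times[-1]))
        apex = srm_signal.detect_peak(
            htrace, window, k=config.detect_k, smooth_width=config.smooth_width
        )
        if apex is None:
            raise StandardFailureError(
                f"heavy standard gave no peak for {assay.peptide_sequence!r} "
                f"fragment {label} in sample {sample_id!r}"
            )
        left, right = srm_signal.peak_bounds(
            htrace, apex, frac=config.bounds_frac, smooth_width=config.smooth_width
        )
        heavy_results.append(srm_signal.integrate_peak(htrace, left, right))
        ltrace = light_traces.get(label)
        if ltrace is None:
            continue
        light_results.append(srm_signal.integrate_peak(ltrace, left, right))
        lapex = srm_signal.detect_peak(
            ltrace,
            (float(ltrace.times[0]), float(ltrace.times[-1])),
            k=config.detect_k,
            smooth_width=config.smooth_width,
        )
        if lapex is not None:
            n_light_detected += 1
            light_apexes.append(lapex)
            heavy_apexes.append(apex)
    heavy_sum = sum_transition_areas(heavy_results)
    light_sum = sum_transition_areas(light_results) if light_results else 0.0
    light_bg = float(sum(r.background for r in light_results))
    ratio = ratio_to_standard(light_sum, heavy_sum)
    light_detected = n_light_detected >= max(1, len(heavy_traces) // 2)
    coel_pass = coel_dev = similarity = None
    if light_apexes:
        coel_pass, coel_dev = srm_signal.coelution_check(
            light_apexes, heavy_apexes, rt_tol=config.rt_tol
        )
    if light_detected and len(light_results) >= 2:
        similarity = srm_signal.transition_rank_similarity(
            [r.area for r in light_results], [r.area for r in heavy_results]
        )
    return PeptideQuant(
        sample_id=sample_id,
        protein_id=assay.protein_id,
        peptide_sequence=assay.peptide_sequence,
        light_area=light_sum,
        heavy_area=heavy_sum,
        ratio_to_standard=ratio,
        light_background=light_bg,
        light_detected=light_detected,
        coelution_pass=coel_pass,
        coelution_max_dev=coel_dev,
        rank_similarity=similarity,
    )


def quantify_cohort(
    panel: AssayPanel,
    runs: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    config: QuantConfig = QuantConfig(),
) -> CohortResult:
    """Run the full normalization and detection chain on a cohort.

    ``runs`` maps sample id → long-format chromatogram table
    (columns sample_id, protein_id, peptide_sequence, is_heavy,
    fragment_label, rt_min, intensity); ``groups`` maps sample id →
    'control' or 'patient'.
    """
    missing = set(runs) - set(groups)
    if missing:
        raise InvalidInputError(f"samples without group labels: {sorted(missing)}")
    sample_ids = list(runs)
    controls = [s for s in sample_ids if groups[s] == "control"]
    if len(controls) < 2:
        raise InvalidInputError("need at least 2 control runs")
    ref_id = panel.reference_protein_id
    if ref_id not in panel.proteins:
        raise ReferenceFailureError(f"reference protein {ref_id!r} not in panel")

    pq_rows: list[PeptideQuant] = []
    for sample_id in sample_ids:
        run = runs[sample_id]
        for protein_id, assays in panel.proteins.items():
            for assay in assays:
                pq_rows.append(quantify_peptide(run, assay, sample_id, config))
    pq = pd.DataFrame([vars(r) for r in pq_rows])

    # reference ratio per sample: mean ratio over the reference's peptides
    ref_ratio = (
        pq[pq["protein_id"] == ref_id]
        .groupby("sample_id")["ratio_to_standard"]
        .mean()
    )
    for sample_id, r in ref_ratio.items():
        if r <= 0:
            raise ReferenceFailureError(
                f"reference ratio non-positive in sample {sample_id!r}"
            )
    ref_stable, ref_cv = reference_stability_check(
        ref_ratio.reindex(sample_ids).to_numpy(), cv_threshold=config.cv_threshold
    )

    # protein ratio per sample: mean over detected candidate peptides,
    # falling back to the quantifier peptide when nothing is detected
    target_ids = [p for p in panel.proteins if p != ref_id]
    ratio_rows = []
    for sample_id in sample_ids:
        for protein_id in target_ids:
            sub = pq[
                (pq["sample_id"] == sample_id) & (pq["protein_id"] == protein_id)
            ]
            detected = sub[sub["light_detected"]]
            quantifier_seq = panel.quantifier_peptide(protein_id).peptide_sequence
            if len(detected):
                protein_ratio = float(detected["ratio_to_standard"].mean())
            else:
                protein_ratio = float(
                    sub[sub["peptide_sequence"] == quantifier_seq][
                        "ratio_to_standard"
                    ].iloc[0]
                )
            ratio_rows.append(
                {
                    "sample_id": sample_id,
                    "protein_id": protein_id,
                    "ratio_to_reference": normalize_to_reference(
                        protein_ratio, float(ref_ratio[sample_id])
                    ),
                }
            )
    protein_ratios = pd.DataFrame(ratio_rows)

    # background models from control runs, one quantifier peptide per protein
    models: dict[str, BackgroundModel] = {}
    for protein_id in target_ids:
        quantifier_seq = panel.quantifier_peptide(protein_id).peptide_sequence
        sub = pq[
            (pq["peptide_sequence"] == quantifier_seq)
            & (pq["sample_id"].isin(controls))
        ]
        mean_signal = float(sub["light_area"].mean())
        models[protein_id] = compute_detection_level(
            sub["light_background"].to_numpy(),
            peptide_sequence=quantifier_seq,
            mean_control_signal=mean_signal,
            z=config.lod_z,
        )

    # percent of controls + detection calls
    ctrl_means = (
        protein_ratios[protein_ratios["sample_id"].isin(controls)]
        .groupby("protein_id")["ratio_to_reference"]
        .mean()
    )
    report_numeric = pd.DataFrame(index=sample_ids, columns=target_ids, dtype=float)
    report = pd.DataFrame(index=sample_ids, columns=target_ids, dtype=object)
    report_numeric.index.name = report.index.name = "sample_id"
    for _i, row in protein_ratios.iterrows():
        s, p = row["sample_id"], row["protein_id"]
        percent = percent_of_controls(
            row["ratio_to_reference"],
            protein_ratios[
                (protein_ratios["protein_id"] == p)
                & (protein_ratios["sample_id"].isin(controls))
            ]["ratio_to_reference"].to_numpy(),
        )
        report_numeric.loc[s, p] = percent
        quantifier_seq = panel.quantifier_peptide(p).peptide_sequence
        area = float(
            pq[
                (pq["sample_id"] == s) & (pq["peptide_sequence"] == quantifier_seq)
            ]["light_area"].iloc[0]
        )
        call = call_detection(area, models[p])
        report.loc[s, p] = "n.d." if call == "n.d." else f"{percent:.0f}"

    detection_levels = pd.DataFrame(
        [
            {
                "protein_id": protein_id,
                "peptide_sequence": m.peptide_sequence,
                "n": m.n,
                "mean_background": m.mean,
                "sd_background": m.sd,
                "detection_level": m.detection_level,
                "detection_level_percent": m.detection_level_percent,
            }
            for protein_id, m in models.items()
        ]
    )
    qc = pq[
        [
            "sample_id",
            "protein_id",
            "peptide_sequence",
            "light_detected",
            "coelution_pass",
            "coelution_max_dev",
            "rank_similarity",
        ]
    ].copy()
    return CohortResult(
        peptide_quants=pq,
        protein_ratios=protein_ratios,
        background_models=models,
        report=report,
        report_numeric=report_numeric,
        detection_levels=detection_levels,
        qc=qc,
        reference_cv=ref_cv,
        reference_stable=ref_stable,
    )
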