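"""Synthetic SRM data with known ground truth.

Generates everything the pipeline consumes: a synthetic proteome whose
six target proteins carry the assay's proteotypic peptides embedded as
tryptic fragments, a fragment-ion spectral library, and whole cohorts
of chromatogram runs (Gaussian elution peaks over truncated-Gaussian
baseline noise, heavy standard spiked at a fixed level, light signal
proportional to true protein abundance).

The default cohort mirrors the study design the pipeline targets:
twelve control runs (two healthy individuals x three biological
replicates x two technical replicates) and four patient samples in
which the two E1 subunits of the branched-chain ketoacid dehydrogenase
complex are truly absent, and one patient additionally lacks MCAD.
Abundances are expressed in percent of the control mean, so ground
truth and pipeline output share a scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay_design import (
    AssayConfig,
    AssayPanel,
    SpectralLibraryEntry,
    build_panel,
)
from .errors import InvalidInputError
from .peptide_chem import (
    AMINO_ACIDS,
    ProteinRecord,
    digest_trypsin,
    write_fasta,
)

# Proteotypic peptides monitored per target protein.  E1A/E1B/E2/E3 are
# the catalytic subunits of the branched-chain ketoacid dehydrogenase
# complex; MCAD is medium-chain acyl-CoA dehydrogenase; HSP60 serves as
# the mitochondrial loading control.  The HSP60 peptides are synthetic
# stand-ins chosen to be plausible tryptic peptides.
TARGET_PEPTIDES: dict[str, tuple[str, ...]] = {
    "E1A": ("VDGNDVFAVYNATK", "AVAENQPFLIEAMTYR"),
    "E1B": ("SGDLFNCGSLTIR", "LGVSCEVIDLR"),
    "E2": ("LSDIGEGIR", "LSEVVGSGK"),
    "E3": ("ALTGGIAHLFK", "EANLAASFGK"),
    "MCAD": ("EEIIPVAAEYDK", "TGEYPVPLIR", "AFTGFIVEADTPGIQIGR", "IYQIYEGTSQIQR"),
    "HSP60": ("TVIIEQSWGSPK", "GVMLAVDAVIAELK"),
}

# Annotated molecular weights (kDa) used by the gel-window filter.
TARGET_MW_KDA: dict[str, float] = {
    "E1A": 50.0,
    "E1B": 43.0,
    "E2": 53.0,
    "E3": 54.0,
    "MCAD": 47.0,
    "HSP60": 61.0,
}

REFERENCE_PROTEIN_ID = "HSP60"

# residues for linkers: no K/R (would add cleavage sites) and no P
# (would block the cleavage that releases an embedded peptide)
_LINKER_ALPHABET = "".join(c for c in AMINO_ACIDS if c not in "KRP")


def _random_linker(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(_LINKER_ALPHABET), size=length)
    return "".join(_LINKER_ALPHABET[i] for i in idx)


def make_proteome(n_decoys: int = 50, seed: int = 0) -> list[ProteinRecord]:
    """Synthetic proteome: six target proteins plus random decoys.

    Each target embeds its peptides between K-terminated linkers so the
    peptides are released intact by tryptic digestion and occur in
    exactly one protein.  Decoys are random sequences guaranteed not to
    contain any target peptide.
    """
    if n_decoys < 0:
        raise InvalidInputError("n_decoys must be non-negative")
    rng = np.random.default_rng(seed)
    all_peptides = [p for peps in TARGET_PEPTIDES.values() for p in peps]
    proteome: list[ProteinRecord] = []
    for protein_id, peptides in TARGET_PEPTIDES.items():
        parts = [_random_linker(rng, int(rng.integers(8, 20))), "K"]
        for pep in peptides:
            parts.append(pep)  # peptides end in K/R, so the next linker is released
            parts.append(_random_linker(rng, int(rng.integers(8, 20))))
            parts.append("K")
        parts.append(_random_linker(rng, int(rng.integers(5, 12))))
        proteome.append(
            ProteinRecord(
                id=protein_id,
                description=f"synthetic scaffold for {protein_id}",
                sequence="".join(parts),
                annotated_mw_kda=TARGET_MW_KDA[protein_id],
            )
        )
    for i in range(n_decoys):
        while True:
            length = int(rng.integers(150, 400))
            idx = rng.integers(0, len(AMINO_ACIDS), size=length)
            seq = "".join(AMINO_ACIDS[j] for j in idx)
            if not any(pep in seq for pep in all_peptides):
                break
        proteome.append(
            ProteinRecord(
                id=f"DECOY{i + 1:03d}",
                description="random decoy protein",
                sequence=seq,
            )
        )
    return proteome


def make_library(
    proteome: Sequence[ProteinRecord],
    seed: int = 0,
    min_fragments: int = 6,
    max_fragments: int = 10,
) -> list[SpectralLibraryEntry]:
    """Spectral library covering the monitored peptides of the targets.

    Library support is what gates peptide candidacy, so entries exist
    exactly for the designated assay peptides.  Each entry carries 6-10
    y-fragments (indices >= 3) with reproducible pseudo-random relative
    intensities in [20, 100], normalised so the strongest fragment is
    100.  Fragment counts and intensities are deterministic in the seed.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for protein in proteome:
        monitored = set(TARGET_PEPTIDES.get(protein.id, ()))
        if not monitored:
            continue
        for pep in digest_trypsin(protein, max_missed=0):
            n = len(pep.sequence)
            if pep.sequence not in monitored:
                continue
            available = list(range(3, n))  # y3 .. y(n-1)
            k = min(len(available), int(rng.integers(min_fragments, max_fragments + 1)))
            chosen = sorted(
                rng.choice(available, size=k, replace=False).tolist()
            )
            raw = rng.uniform(20.0, 100.0, size=k)
            raw = raw / raw.max() * 100.0
            fragments = tuple(
                (f"y{idx}", 1, round(float(inten), 4))
                for idx, inten in zip(chosen, raw)
            )
            entries.append(
                SpectralLibraryEntry(
                    peptide_sequence=pep.sequence,
                    precursor_charge=2,
                    fragments=fragments,
                )
            )
    return entries


# Default patient abundance pattern (percent of control mean): the E1
# subunits are truly absent in all patients; patient 4 additionally
# lacks MCAD; E2/E3 sit near or somewhat above control levels.
DEFAULT_PATIENTS: tuple[tuple[str, dict[str, float]], ...] = (
    ("patient1", {"E1A": 0.0, "E1B": 0.0, "E2": 152.0, "E3": 110.0, "MCAD": 181.0}),
    ("patient2", {"E1A": 0.0, "E1B": 0.0, "E2": 102.0, "E3": 106.0, "MCAD": 89.0}),
    ("patient3", {"E1A": 0.0, "E1B": 0.0, "E2": 136.0, "E3": 124.0, "MCAD": 124.0}),
    ("patient4", {"E1A": 0.0, "E1B": 0.0, "E2": 100.0, "E3": 110.0, "MCAD": 0.0}),
)


@dataclass
class ScenarioConfig:
    """Cohort design and instrument-response parameters.

    Abundances are percent of the control mean (controls are 100 for
    every protein).  ``heavy_spike_level`` and ``light_base_amplitude``
    are arbitrary intensity units; ``noise_sd`` sets baseline noise and
    hence signal-to-noise (default amplitudes give S/N well above 50).
    """

    n_control_runs: int = 12
    patients: tuple[tuple[str, dict[str, float]], ...] = DEFAULT_PATIENTS
    heavy_spike_level: float = 1000.0
    light_base_amplitude: float = 800.0
    baseline_level: float = 20.0
    noise_sd: float = 2.0
    rt_start: float = 10.0       # first peptide elutes here (min)
    rt_spacing: float = 1.5      # between consecutive peptides (min)
    rt_sigma: float = 0.05       # Gaussian peak width (min)
    rt_halfwindow: float = 0.9   # trace extends this far around the apex (min)
    dt: float = 0.01             # sampling interval (min)
    rt_jitter: float = 0.05      # max light-vs-heavy apex offset (min)
    loading_sigma: float = 0.15  # lognormal SD of per-sample loading factor
    n_decoys: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")
        for _pid, abundances in self.patients:
            if any(v < 0 for v in abundances.values()):
                raise InvalidInputError("abundances must be non-negative")


@dataclass
class CohortDataset:
    """In-memory synthetic cohort plus its ground truth."""

    proteome: list[ProteinRecord]
    library: list[SpectralLibraryEntry]
    panel: AssayPanel
    runs: dict[str, pd.DataFrame]
    groups: dict[str, str]
    truth_abundance: pd.DataFrame   # sample x protein true percent
    truth_areas: pd.DataFrame       # injected analytic areas per trace
    scenario: ScenarioConfig


def _rt_centers(panel: AssayPanel, config: ScenarioConfig) -> dict[str, float]:
    peptides = sorted(
        {a.peptide_sequence for assays in panel.proteins.values() for a in assays}
    )
    return {
        pep: config.rt_start + i * config.rt_spacing
        for i, pep in enumerate(peptides)
    }


def simulate_run(
    panel: AssayPanel,
    abundances: Mapping[str, float],
    config: ScenarioConfig,
    seed: int,
    sample_id: str = "run",
    response_factors: Mapping[str, float] | None = None,
    loading_factor: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one SRM run over every transition in the panel.

    Per transition the trace is a Gaussian elution peak on a
    truncated-Gaussian noise baseline.  Heavy amplitude follows the
    fixed spike level; light amplitude is proportional to the protein's
    true abundance times the per-sample loading factor.  Light and
    heavy apexes agree up to a small retention-time jitter.

    Returns (long-format chromatogram table, ground-truth analytic areas).
    """
    rng = np.random.default_rng(seed)
    centers = _rt_centers(panel, config)
    response_factors = response_factors or {}
    rows = []
    truth_rows = []
    for protein_id, assays in panel.proteins.items():
        abundance = abundances.get(protein_id, 100.0)
        for assay in assays:
            pep = assay.peptide_sequence
            rf = response_factors.get(pep, 1.0)
            center = centers[pep]
            jitter = rng.uniform(-config.rt_jitter, config.rt_jitter)
            heavy_apex = center
            light_apex = center + jitter
            times = np.arange(
                center - config.rt_halfwindow,
                center + config.rt_halfwindow + config.dt / 2,
                config.dt,
            )
            for t_light, t_heavy in zip(assay.light, assay.heavy):
                # fragment weight decays with library rank, so the observed
                # transition ranking reproduces the library ranking
                rel = 1.0 / t_light.library_rank ** 0.5
                amp_heavy = config.heavy_spike_level * rf * rel
                amp_light = (
                    config.light_base_amplitude
                    * (abundance / 100.0)
                    * loading_factor
                    * rf
                    * rel
                )
                for is_heavy, amp, apex, tdef in (
                    (False, amp_light, light_apex, t_light),
                    (True, amp_heavy, heavy_apex, t_heavy),
                ):
                    signal = amp * np.exp(
                        -0.5 * ((times - apex) / config.rt_sigma) ** 2
                    )
                    noise = config.baseline_level + config.noise_sd * rng.standard_normal(
                        times.size
                    )
                    trace = np.maximum(signal + noise, 0.0)
                    for t, y in zip(times, trace):
                        rows.append(
                            (
                                sample_id,
                                protein_id,
                                pep,
                                int(is_heavy),
                                tdef.fragment_label,
                                round(float(t), 4),
                                round(float(y), 4),
                            )
                        )
                    truth_rows.append(
                        {
                            "sample_id": sample_id,
                            "protein_id": protein_id,
                            "peptide_sequence": pep,
                            "is_heavy": int(is_heavy),
                            "fragment_label": tdef.fragment_label,
                            "apex_rt": apex,
                            "amplitude": amp,
                            "analytic_area": amp
                            * config.rt_sigma
                            * float(np.sqrt(2 * np.pi)),
                        }
                    )
    run = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "protein_id",
            "peptide_sequence",
            "is_heavy",
            "fragment_label",
            "rt_min",
            "intensity",
        ],
    )
    return run, pd.DataFrame(truth_rows)


def make_cohort(
    scenario: ScenarioConfig | None = None,
    outdir: str | Path | None = None,
) -> CohortDataset:
    """Build the full synthetic cohort: proteome, library, panel and runs.

    Controls sit at 100% for every protein; patient abundances follow
    the scenario.  With ``outdir`` the dataset is also written to disk
    (FASTA proteome, library CSV, transition list, per-sample
    chromatogram TSVs, ground-truth TSVs, scenario JSON, manifest).
    """
    scenario = scenario or ScenarioConfig()
    seedseq = np.random.SeedSequence(scenario.seed)
    child = seedseq.generate_state(4, dtype=np.uint32)
    proteome = make_proteome(scenario.n_decoys, seed=int(child[0]))
    library = make_library(proteome, seed=int(child[1]))
    targets = [p for p in proteome if p.id in TARGET_PEPTIDES]
    digests = {p.id: digest_trypsin(p, max_missed=0) for p in targets}
    panel = build_panel(
        targets,
        digests,
        library,
        proteome,
        AssayConfig(reference_protein_id=REFERENCE_PROTEIN_ID),
    )
    rng = np.random.default_rng(int(child[2]))
    peptides = sorted(
        {a.peptide_sequence for assays in panel.proteins.values() for a in assays}
    )
    response_factors = {
        pep: float(np.exp(rng.normal(0.0, 0.2))) for pep in peptides
    }

    samples: list[tuple[str, str, dict[str, float]]] = []
    for i in range(scenario.n_control_runs):
        samples.append((f"control{i + 1:02d}", "control", {}))
    for pid, abundances in scenario.patients:
        samples.append((pid, "patient", dict(abundances)))

    run_seeds = np.random.SeedSequence(int(child[3])).generate_state(
        len(samples), dtype=np.uint32
    )
    runs: dict[str, pd.DataFrame] = {}
    groups: dict[str, str] = {}
    truth_area_frames = []
    truth_rows = []
    loading_rng = np.random.default_rng(int(child[2]) ^ 0x5EED)
    for (sample_id, group, abundances), rseed in zip(samples, run_seeds):
        loading = float(np.exp(loading_rng.normal(0.0, scenario.loading_sigma)))
        run, truth = simulate_run(
            panel,
            abundances,
            scenario,
            seed=int(rseed),
            sample_id=sample_id,
            response_factors=response_factors,
            loading_factor=loading,
        )
        runs[sample_id] = run
        groups[sample_id] = group
        truth_area_frames.append(truth)
        for protein_id in panel.proteins:
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "protein_id": protein_id,
                    "true_percent": abundances.get(protein_id, 100.0),
                }
            )
    dataset = CohortDataset(
        proteome=proteome,
        library=library,
        panel=panel,
        runs=runs,
        groups=groups,
        truth_abundance=pd.DataFrame(truth_rows),
        truth_areas=pd.concat(truth_area_frames, ignore_index=True),
        scenario=scenario,
    )
    if outdir is not None:
        write_cohort(dataset, outdir)
    return dataset


def write_library_csv(
    library: Sequence[SpectralLibraryEntry], path: str | Path
) -> None:
    rows = []
    for entry in library:
        for label, charge, intensity in entry.fragments:
            rows.append(
                {
                    "peptide_sequence": entry.peptide_sequence,
                    "precursor_charge": entry.precursor_charge,
                    "fragment_label": label,
                    "fragment_charge": charge,
                    "relative_intensity": intensity,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_library_csv(path: str | Path) -> list[SpectralLibraryEntry]:
    df = pd.read_csv(path)
    entries = []
    for (pep, charge), group in df.groupby(
        ["peptide_sequence", "precursor_charge"], sort=True
    ):
        fragments = tuple(
            (str(r.fragment_label), int(r.fragment_charge), float(r.relative_intensity))
            for r in group.itertuples(index=False)
        )
        entries.append(
            SpectralLibraryEntry(
                peptide_sequence=str(pep),
                precursor_charge=int(charge),
                fragments=fragments,
            )
        )
    return entries


def write_cohort(dataset: CohortDataset, outdir: str | Path) -> dict[str, str]:
    """Write every dataset artifact to ``outdir``; returns the manifest
    (relative path → sha256)."""
    from .assay_design import write_transition_list

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.proteome, out / "proteome.fasta")
    write_library_csv(dataset.library, out / "library.csv")
    write_transition_list(dataset.panel, out / "transitions.csv")
    runs_dir = out / "runs"
    runs_dir.mkdir(exist_ok=True)
    for sample_id, run in dataset.runs.items():
        run.to_csv(runs_dir / f"{sample_id}.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"sample_id": s, "group": g} for s, g in dataset.groups.items()]
    ).to_csv(out / "samples.csv", index=False)
    dataset.truth_abundance.to_csv(out / "truth_abundance.tsv", sep="\t", index=False)
    dataset.truth_areas.to_csv(
        out / "truth_areas.tsv", sep="\t", index=False, float_format="%.6f"
    )
    scenario_dict = {
        k: v for k, v in vars(dataset.scenario).items() if k != "patients"
    }
    scenario_dict["patients"] = [
        {"sample_id": pid, "abundances": ab} for pid, ab in dataset.scenario.patients
    ]
    (out / "scenario.json").write_text(json.dumps(scenario_dict, indent=2))
    manifest = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_cohort_runs(
    dataset_dir: str | Path,
) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Load per-sample chromatogram TSVs and group labels from disk."""
    root = Path(dataset_dir)
    samples = pd.read_csv(root / "samples.csv")
    groups = dict(zip(samples["sample_id"], samples["group"]))
    runs = {}
    for path in sorted((root / "runs").glob("*.tsv")):
        df = pd.read_csv(path, sep="\t")
        runs[path.stem] = df
    return runs, groups
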