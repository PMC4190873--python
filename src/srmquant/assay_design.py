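"""Assay-panel construction for SRM.

Per protein, two to four proteotypic peptide candidates are selected on
the basis of proteome uniqueness and spectral-library fragment
intensity; per peptide, the five most intense eligible y-fragment
transitions.  Each light transition is paired with a heavy-labelled
counterpart targeting the same fragment, and the panel designates one
quantifier peptide per protein plus a reference protein acting as the
loading control.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import AssayDesignWarning, InvalidInputError
from .peptide_chem import (
    DEFAULT_TABLE,
    Peptide,
    ProteinRecord,
    ResidueMassTable,
    precursor_mz,
    proteome_uniqueness,
    y_ion_mz,
)

_ION_LABEL_RE = re.compile(r"^([aby])(\d+)$")


@dataclass(frozen=True)
class SpectralLibraryEntry:
    """Fragment-ion intensities for one peptide precursor.

    ``fragments`` holds (ion label such as "y7", fragment charge,
    relative intensity >= 0) triples.
    """

    peptide_sequence: str
    precursor_charge: int
    fragments: tuple[tuple[str, int, float], ...]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise InvalidInputError(
                f"library entry for {self.peptide_sequence!r} has no fragments"
            )
        for label, _charge, intensity in self.fragments:
            if parse_ion_label(label) is None:
                raise InvalidInputError(f"unparseable ion label {label!r}")
            if not (intensity >= 0 and intensity == intensity):
                raise InvalidInputError(
                    f"invalid intensity {intensity!r} for {label!r}"
                )


def parse_ion_label(label: str) -> tuple[str, int] | None:
    """Split an ion label like 'y7' into ('y', 7); None if unparseable."""
    m = _ION_LABEL_RE.match(label)
    if m is None:
        return None
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class TransitionDefinition:
    """One monitored precursor/product m/z pair."""

    protein_id: str
    peptide_sequence: str
    is_heavy: bool
    precursor_charge: int
    precursor_mz: float
    fragment_label: str
    fragment_charge: int
    product_mz: float
    library_rank: int

    @property
    def trace_key(self) -> tuple[str, str, bool, str]:
        return (self.protein_id, self.peptide_sequence, self.is_heavy,
                self.fragment_label)


@dataclass(frozen=True)
class PeptideAssay:
    """Light/heavy transition sets for one candidate peptide."""

    protein_id: str
    peptide_sequence: str
    candidate_rank: int
    light: tuple[TransitionDefinition, ...]
    heavy: tuple[TransitionDefinition, ...]


@dataclass
class AssayPanel:
    """Per-protein peptide assays plus the reference-protein designation."""

    proteins: dict[str, list[PeptideAssay]]
    reference_protein_id: str

    def quantifier_peptide(self, protein_id: str) -> PeptideAssay:
        """The designated (top-ranked) quantifier peptide for a protein."""
        return self.proteins[protein_id][0]

    def all_transitions(self) -> list[TransitionDefinition]:
        out = []
        for assays in self.proteins.values():
            for assay in assays:
                out.extend(assay.light)
                out.extend(assay.heavy)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssayPanel):
            return NotImplemented
        return (
            self.reference_protein_id == other.reference_protein_id
            and self.proteins == other.proteins
        )


@dataclass(frozen=True)
class AssayConfig:
    """Tunable assay-design parameters."""

    min_peptides: int = 2
    max_peptides: int = 4
    n_transitions: int = 5
    precursor_charge: int = 2
    fragment_charge: int = 1
    min_fragment_index: int = 3  # y1/y2 considered unspecific
    min_peptide_length: int = 7
    max_peptide_length: int = 25
    reference_protein_id: str = "HSP60"
    uniqueness_max_missed: int = 2
    table: ResidueMassTable = field(default_factory=lambda: DEFAULT_TABLE)


def _eligible_fragments(
    entry: SpectralLibraryEntry, min_index: int, peptide_length: int
) -> list[tuple[str, int, float, int]]:
    """y-ions with index in [min_index, length-1]: (label, charge, intensity, index)."""
    out = []
    for label, charge, intensity in entry.fragments:
        parsed = parse_ion_label(label)
        if parsed is None:
            continue
        ion_type, index = parsed
        if ion_type != "y":
            continue
        if index < min_index or index >= peptide_length:
            continue
        out.append((label, charge, intensity, index))
    return out


def select_transitions(
    entry: SpectralLibraryEntry,
    n: int = 5,
    *,
    protein_id: str = "",
    is_heavy: bool = False,
    config: AssayConfig = AssayConfig(),
) -> list[TransitionDefinition]:
    """Select the ``n`` most intense eligible y-fragment transitions.

    Eligibility: y-ions with fragment index >= config.min_fragment_index.
    Ties break on higher product m/z, then lexicographic fragment label,
    so selection is deterministic.  If fewer than ``n`` eligible fragments
    exist, all are returned and a shortfall warning is issued.
    """
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    pep = Peptide(sequence=entry.peptide_sequence, is_heavy=is_heavy)
    length = len(entry.peptide_sequence)
    eligible = _eligible_fragments(entry, config.min_fragment_index, length)
    if not eligible:
        warnings.warn(
            f"no eligible y-fragments for {entry.peptide_sequence!r}",
            AssayDesignWarning,
            stacklevel=2,
        )
        return []
    pre_mz = precursor_mz(pep, config.precursor_charge, config.table)
    scored = []
    for label, charge, intensity, index in eligible:
        prod_mz = y_ion_mz(pep, index, charge, config.table)
        scored.append((intensity, prod_mz, label, charge))
    # descending intensity; ties: higher product m/z, then label
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    chosen = scored[:n]
    if len(chosen) < n:
        warnings.warn(
            f"only {len(chosen)} eligible fragments for "
            f"{entry.peptide_sequence!r} (requested {n})",
            AssayDesignWarning,
            stacklevel=2,
        )
    return [
        TransitionDefinition(
            protein_id=protein_id,
            peptide_sequence=entry.peptide_sequence,
            is_heavy=is_heavy,
            precursor_charge=config.precursor_charge,
            precursor_mz=pre_mz,
            fragment_label=label,
            fragment_charge=charge,
            product_mz=prod_mz,
            library_rank=rank,
        )
        for rank, (intensity, prod_mz, label, charge) in enumerate(chosen, start=1)
    ]


def _library_index(
    library: Sequence[SpectralLibraryEntry],
) -> dict[str, SpectralLibraryEntry]:
    return {entry.peptide_sequence: entry for entry in library}


def select_peptide_candidates(
    protein: ProteinRecord,
    digest: Sequence[Peptide],
    library: Sequence[SpectralLibraryEntry],
    proteome: Sequence[ProteinRecord],
    min_n: int = 2,
    max_n: int = 4,
    config: AssayConfig = AssayConfig(),
) -> list[Peptide]:
    """Rank and select proteotypic peptide candidates for one protein.

    Candidates must be proteome-unique, library-supported, within the
    configured length bounds and end in K or R (so a heavy-labelled
    counterpart exists).  Ranking is by summed intensity of each
    peptide's top eligible fragments (up to ``config.n_transitions``),
    descending; ties break lexicographically on sequence.
    """
    if min_n > max_n:
        raise InvalidInputError("min_n must be <= max_n")
    if not digest:
        raise InvalidInputError(f"empty digest for protein {protein.id!r}")
    lib = _library_index(library)
    scored: list[tuple[float, str, Peptide]] = []
    seen: set[str] = set()
    for pep in digest:
        seq = pep.sequence
        if seq in seen:
            continue
        seen.add(seq)
        if not config.min_peptide_length <= len(seq) <= config.max_peptide_length:
            continue
        if seq[-1] not in "KR":
            continue
        entry = lib.get(seq)
        if entry is None:
            continue
        eligible = _eligible_fragments(entry, config.min_fragment_index, len(seq))
        if not eligible:
            continue
        if (
            proteome_uniqueness(
                seq, proteome, max_missed=config.uniqueness_max_missed
            )
            != 1
        ):
            continue
        intensities = sorted((f[2] for f in eligible), reverse=True)
        score = sum(intensities[: config.n_transitions])
        scored.append((score, seq, pep))
    scored.sort(key=lambda t: (-t[0], t[1]))
    selected = [pep for _score, _seq, pep in scored[:max_n]]
    if len(selected) < min_n:
        warnings.warn(
            f"protein {protein.id!r}: only {len(selected)} eligible peptide "
            f"candidate(s), fewer than the requested minimum {min_n}",
            AssayDesignWarning,
            stacklevel=2,
        )
    return selected


def build_panel(
    proteins: Sequence[ProteinRecord],
    digests: dict[str, Sequence[Peptide]],
    library: Sequence[SpectralLibraryEntry],
    proteome: Sequence[ProteinRecord],
    config: AssayConfig = AssayConfig(),
) -> AssayPanel:
    """Assemble the full assay panel with paired light/heavy transitions.

    The quantifier peptide for each protein is the top-ranked candidate.
    A protein without any library-supported peptide is dropped with a
    warning, except the reference protein, whose absence is a hard error
    because normalization would be impossible.
    """
    if not library:
        raise InvalidInputError(
            "empty spectral library; no protein has library support: "
            + ", ".join(p.id for p in proteins)
        )
    if config.reference_protein_id not in {p.id for p in proteins}:
        raise InvalidInputError(
            f"reference protein {config.reference_protein_id!r} not among inputs"
        )
    lib = _library_index(library)
    panel_proteins: dict[str, list[PeptideAssay]] = {}
    for protein in proteins:
        candidates = select_peptide_candidates(
            protein,
            digests[protein.id],
            library,
            proteome,
            min_n=config.min_peptides,
            max_n=config.max_peptides,
            config=config,
        )
        assays = []
        for rank, pep in enumerate(candidates, start=1):
            entry = lib[pep.sequence]
            light = select_transitions(
                entry,
                config.n_transitions,
                protein_id=protein.id,
                is_heavy=False,
                config=config,
            )
            heavy = select_transitions(
                entry,
                config.n_transitions,
                protein_id=protein.id,
                is_heavy=True,
                config=config,
            )
            assays.append(
                PeptideAssay(
                    protein_id=protein.id,
                    peptide_sequence=pep.sequence,
                    candidate_rank=rank,
                    light=tuple(light),
                    heavy=tuple(heavy),
                )
            )
        if assays:
            panel_proteins[protein.id] = assays
        elif protein.id == config.reference_protein_id:
            raise InvalidInputError(
                f"reference protein {protein.id!r} yields no assayable "
                "peptides; normalization impossible"
            )
        else:
            warnings.warn(
                f"protein {protein.id!r} has no assayable peptides and is "
                "dropped from the panel",
                AssayDesignWarning,
                stacklevel=2,
            )
    return AssayPanel(
        proteins=panel_proteins,
        reference_protein_id=config.reference_protein_id,
    )


TRANSITION_COLUMNS = [
    "protein_id",
    "peptide_sequence",
    "is_heavy",
    "precursor_charge",
    "precursor_mz",
    "fragment_label",
    "fragment_charge",
    "product_mz",
    "library_rank",
]


def write_transition_list(panel: AssayPanel, path: str | Path) -> None:
    """Serialize a panel to CSV (one row per transition).

    Candidate order is preserved by row order; the reference protein is
    recorded in a leading comment line so the file round-trips exactly.
    """
    rows = []
    for assays in panel.proteins.values():
        for assay in assays:
            for t in list(assay.light) + list(assay.heavy):
                rows.append(
                    {
                        "protein_id": t.protein_id,
                        "peptide_sequence": t.peptide_sequence,
                        "is_heavy": int(t.is_heavy),
                        "precursor_charge": t.precursor_charge,
                        "precursor_mz": f"{t.precursor_mz:.6f}",
                        "fragment_label": t.fragment_label,
                        "fragment_charge": t.fragment_charge,
                        "product_mz": f"{t.product_mz:.6f}",
                        "library_rank": t.library_rank,
                    }
                )
    df = pd.DataFrame(rows, columns=TRANSITION_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# reference_protein_id={panel.reference_protein_id}\n")
        df.to_csv(fh, index=False)


def read_transition_list(path: str | Path) -> AssayPanel:
    """Parse a transition-list CSV back into an AssayPanel."""
    with open(path) as fh:
        first = fh.readline()
        reference = "HSP60"
        if first.startswith("# reference_protein_id="):
            reference = first.split("=", 1)[1].strip()
            header_line = 1
        else:
            fh.seek(0)
            header_line = 0
        try:
            df = pd.read_csv(fh)
        except Exception as exc:
            raise InvalidInputError(f"malformed transition list: {exc}") from exc
    missing = set(TRANSITION_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(
            f"transition list missing column(s) {sorted(missing)} "
            f"(header at line {header_line + 1})"
        )
    panel_proteins: dict[str, list[PeptideAssay]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=header_line + 2):
        try:
            t = TransitionDefinition(
                protein_id=str(row.protein_id),
                peptide_sequence=str(row.peptide_sequence),
                is_heavy=bool(int(row.is_heavy)),
                precursor_charge=int(row.precursor_charge),
                precursor_mz=float(row.precursor_mz),
                fragment_label=str(row.fragment_label),
                fragment_charge=int(row.fragment_charge),
                product_mz=float(row.product_mz),
                library_rank=int(row.library_rank),
            )
        except (TypeError, ValueError) as exc:
            raise InvalidInputError(f"malformed row at line {row_no}: {exc}") from exc
        assays = panel_proteins.setdefault(t.protein_id, [])
        for assay in assays:
            if assay.peptide_sequence == t.peptide_sequence:
                target = assay
                break
        else:
            target = PeptideAssay(
                protein_id=t.protein_id,
                peptide_sequence=t.peptide_sequence,
                candidate_rank=len(assays) + 1,
                light=(),
                heavy=(),
            )
            assays.append(target)
        idx = assays.index(target)
        if t.is_heavy:
            assays[idx] = PeptideAssay(
                protein_id=target.protein_id,
                peptide_sequence=target.peptide_sequence,
                candidate_rank=target.candidate_rank,
                light=target.light,
                heavy=target.heavy + (t,),
            )
        else:
            assays[idx] = PeptideAssay(
                protein_id=target.protein_id,
                peptide_sequence=target.peptide_sequence,
                candidate_rank=target.candidate_rank,
                light=target.light + (t,),
                heavy=target.heavy,
            )
    return AssayPanel(proteins=panel_proteins, reference_protein_id=reference)
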