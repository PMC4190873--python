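"""Residue-level mass chemistry for SRM assay design.

Tryptic digestion, peptide and y-ion fragment masses, fixed and
stable-isotope modifications, proteome-uniqueness screening and the
gel molecular-weight window filter.

Mass conventions
----------------
All m/z arithmetic uses monoisotopic residue masses (from pyteomics);
average masses are used only for whole-protein molecular weight, which
is what a gel separates on.  Heavy internal standards carry a
C-terminal isotope label: +8.014199 Da on Lys (13C6 15N2) or
+10.008269 Da on Arg (13C6 15N4) — nominally "+8/+10 Da".
Carbamidomethylation of cysteine (+57.02146 Da) is treated as a fixed
modification on every C, mirroring alkylation during sample
preparation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

from .errors import InvalidInputError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PROTON_MASS = 1.00727646688
WATER_MONO = _pmass.calculate_mass(formula="H2O")  # 18.0105646837

CARBAMIDOMETHYL = 57.02146
HEAVY_LYS = 8.014199   # 13C6 15N2
HEAVY_ARG = 10.008269  # 13C6 15N4


def _average_residue_masses() -> dict[str, float]:
    return {
        aa: _pmass.calculate_mass(composition=_pmass.std_aa_comp[aa], average=True)
        for aa in AMINO_ACIDS
    }


@dataclass(frozen=True)
class ResidueMassTable:
    """Residue masses plus fixed and isotope-label modification deltas.

    The default table takes monoisotopic and average residue masses from
    pyteomics, applies carbamidomethyl as a fixed modification on C, and
    defines heavy labels for the tryptic C-terminal residues K and R.
    """

    residue_monoisotopic: dict[str, float] = field(
        default_factory=lambda: {aa: _pmass.std_aa_mass[aa] for aa in AMINO_ACIDS}
    )
    residue_average: dict[str, float] = field(default_factory=_average_residue_masses)
    water_mono: float = WATER_MONO
    proton: float = PROTON_MASS
    fixed_mods: dict[str, float] = field(
        default_factory=lambda: {"C": CARBAMIDOMETHYL}
    )
    heavy_labels: dict[str, float] = field(
        default_factory=lambda: {"K": HEAVY_LYS, "R": HEAVY_ARG}
    )

    def __post_init__(self) -> None:
        for aa in AMINO_ACIDS:
            if aa not in self.residue_monoisotopic or aa not in self.residue_average:
                raise InvalidInputError(f"mass table missing residue {aa!r}")
        for name, mapping in (
            ("monoisotopic", self.residue_monoisotopic),
            ("average", self.residue_average),
        ):
            for aa, m in mapping.items():
                if not m > 0:
                    raise InvalidInputError(f"non-positive {name} mass for {aa!r}")
        if set(self.heavy_labels) != {"K", "R"}:
            raise InvalidInputError("heavy labels must be defined exactly for K and R")
        if "C" not in self.fixed_mods:
            raise InvalidInputError("fixed modifications must include C")

    @classmethod
    def from_json(cls, path: str | Path) -> "ResidueMassTable":
        """Load overrides from a JSON config; unspecified fields keep defaults."""
        with open(path) as fh:
            cfg = json.load(fh)
        table = cls()
        updates = {}
        for key in (
            "residue_monoisotopic",
            "residue_average",
            "fixed_mods",
            "heavy_labels",
        ):
            if key in cfg:
                merged = dict(getattr(table, key))
                merged.update(cfg[key])
                updates[key] = merged
        for key in ("water_mono", "proton"):
            if key in cfg:
                updates[key] = float(cfg[key])
        return replace(table, **updates)


DEFAULT_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identity and optional annotated weight (kDa)."""

    id: str
    description: str
    sequence: str
    annotated_mw_kda: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise InvalidInputError(
                f"protein {self.id!r} contains non-standard residue(s) "
                f"{sorted(bad)!r}"
            )


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide located within one or more parent proteins.

    Positions are 1-based inclusive.  ``mods`` lists variable
    (position, mass delta) pairs; fixed modifications and the heavy
    label are resolved from the mass table at mass-computation time.
    """

    sequence: str
    parent_ids: tuple[str, ...] = ()
    start: int = 1
    end: int = 0
    missed_cleavages: int = 0
    is_heavy: bool = False
    mods: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError("empty peptide sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise InvalidInputError(
                f"peptide {self.sequence!r} contains non-standard residue(s) "
                f"{sorted(bad)!r}"
            )
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)

    def as_heavy(self) -> "Peptide":
        return replace(self, is_heavy=True)

    def as_light(self) -> "Peptide":
        return replace(self, is_heavy=False)


def _coerce(peptide: Peptide | str) -> Peptide:
    return peptide if isinstance(peptide, Peptide) else Peptide(sequence=peptide)


def _cleavage_boundaries(sequence: str) -> list[int]:
    """0-based indices after which trypsin cleaves (K/R not followed by P)."""
    cuts = []
    n = len(sequence)
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 == n or sequence[i + 1] != "P"):
            if i + 1 < n:
                cuts.append(i)
    return cuts


def digest_trypsin(protein: ProteinRecord, max_missed: int = 0) -> list[Peptide]:
    """In-silico tryptic digest: cleave after K/R except before P.

    Returns all peptides with 0..``max_missed`` missed cleavages, ordered
    by start position then length.
    """
    if max_missed < 0:
        raise InvalidInputError("max_missed must be non-negative")
    seq = protein.sequence
    cuts = _cleavage_boundaries(seq)
    # segment boundaries: [start, end] 0-based inclusive
    starts = [0] + [c + 1 for c in cuts]
    ends = cuts + [len(seq) - 1]
    peptides = []
    nseg = len(starts)
    for i in range(nseg):
        for mc in range(0, max_missed + 1):
            j = i + mc
            if j >= nseg:
                break
            s, e = starts[i], ends[j]
            peptides.append(
                Peptide(
                    sequence=seq[s : e + 1],
                    parent_ids=(protein.id,),
                    start=s + 1,
                    end=e + 1,
                    missed_cleavages=mc,
                )
            )
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


def peptide_mass(
    peptide: Peptide | str,
    table: ResidueMassTable = DEFAULT_TABLE,
    monoisotopic: bool = True,
) -> float:
    """Neutral peptide mass in Da, including fixed mods, variable mods and
    the heavy label when the peptide is flagged heavy."""
    pep = _coerce(peptide)
    residues = table.residue_monoisotopic if monoisotopic else table.residue_average
    try:
        m = sum(residues[aa] for aa in pep.sequence)
    except KeyError as exc:
        raise InvalidInputError(f"unknown residue {exc.args[0]!r}") from exc
    m += table.water_mono
    m += sum(table.fixed_mods.get(aa, 0.0) for aa in pep.sequence)
    m += sum(delta for _pos, delta in pep.mods)
    if pep.is_heavy:
        terminal = pep.sequence[-1]
        if terminal not in table.heavy_labels:
            raise InvalidInputError(
                f"cannot heavy-label peptide ending in {terminal!r}; "
                "labels exist for K and R only"
            )
        m += table.heavy_labels[terminal]
    return m


def precursor_mz(
    peptide: Peptide | str,
    charge: int,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """Precursor m/z = (M + z·proton) / z."""
    if charge < 1:
        raise InvalidInputError(f"charge must be >= 1, got {charge}")
    return (peptide_mass(peptide, table) + charge * table.proton) / charge


def y_ion_mz(
    peptide: Peptide | str,
    index: int,
    charge: int = 1,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """m/z of the y_index fragment (C-terminal ``index`` residues).

    Fixed modifications, variable modifications and the heavy label are
    included when they fall inside the fragment; y ions always contain the
    labelled C-terminal residue.
    """
    pep = _coerce(peptide)
    n = len(pep.sequence)
    if not 1 <= index < n:
        raise InvalidInputError(
            f"y-ion index must be in [1, {n - 1}] for a {n}-residue peptide, "
            f"got {index}"
        )
    if charge < 1:
        raise InvalidInputError(f"charge must be >= 1, got {charge}")
    frag_start = n - index  # 0-based
    frag = pep.sequence[frag_start:]
    residues = table.residue_monoisotopic
    m = sum(residues[aa] for aa in frag) + table.water_mono
    m += sum(table.fixed_mods.get(aa, 0.0) for aa in frag)
    m += sum(delta for pos, delta in pep.mods if pos - 1 >= frag_start)
    if pep.is_heavy:
        m += table.heavy_labels[pep.sequence[-1]]
    return (m + charge * table.proton) / charge


def _match_key(sequence: str, equate_il: bool) -> str:
    return sequence.replace("I", "L") if equate_il else sequence


@lru_cache(maxsize=8192)
def _digest_key_set(
    protein: ProteinRecord, max_missed: int, equate_il: bool
) -> frozenset[str]:
    return frozenset(
        _match_key(p.sequence, equate_il)
        for p in digest_trypsin(protein, max_missed=max_missed)
    )


def proteome_uniqueness(
    peptide_sequence: str,
    proteome: Sequence[ProteinRecord],
    equate_il: bool = False,
    max_missed: int = 2,
) -> int:
    """Number of distinct proteins whose tryptic digest contains the peptide.

    A proteotypic peptide returns 1.  With ``equate_il`` the
    mass-indistinguishable residues I and L are treated as equal during
    matching (off by default).
    """
    if not peptide_sequence:
        raise InvalidInputError("empty peptide sequence")
    if not proteome:
        raise InvalidInputError("empty proteome")
    key = _match_key(peptide_sequence, equate_il)
    count = 0
    for protein in proteome:
        if key in _digest_key_set(protein, max_missed, equate_il):
            count += 1
    return count


def protein_average_mass_kda(
    protein: ProteinRecord, table: ResidueMassTable = DEFAULT_TABLE
) -> float:
    """Average (chemical) molecular weight of the intact chain, in kDa."""
    m = sum(table.residue_average[aa] for aa in protein.sequence) + table.water_mono
    return m / 1000.0


def gel_window_filter(
    proteins: Iterable[ProteinRecord],
    low_kda: float = 25.0,
    high_kda: float = 60.0,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[ProteinRecord]:
    """Keep proteins whose molecular weight lies in [low, high] kDa (inclusive).

    Emulates excising the central region of an SDS-PAGE lane.  The
    annotated weight is used when present; otherwise the average mass is
    computed from the sequence.
    """
    if not low_kda < high_kda:
        raise InvalidInputError("low_kda must be strictly less than high_kda")
    kept = []
    for protein in proteins:
        mw = (
            protein.annotated_mw_kda
            if protein.annotated_mw_kda is not None
            else protein_average_mass_kda(protein, table)
        )
        if low_kda <= mw <= high_kda:
            kept.append(protein)
    return kept


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome FASTA; the description line is 'accession description'."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                id=rec.id,
                description=rec.description[len(rec.id) :].strip(),
                sequence=str(rec.seq).upper(),
            )
        )
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            header = f">{p.id} {p.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")
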