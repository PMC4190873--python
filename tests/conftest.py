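"""Shared fixtures: brute-force oracles and a session-scoped synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from srmquant.peptide_chem import ProteinRecord
from srmquant.quantify import quantify_cohort
from srmquant.synthetic_data import ScenarioConfig, make_cohort

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def oracle_digest(sequence: str, max_missed: int) -> set[tuple[int, int, str]]:
    """Enumerate all (start, end) substrings that are valid tryptic peptides.

    A substring [i, j] (0-based inclusive) is valid when its left edge is
    the protein start or follows a cleavage site, its right edge is the
    protein end or a cleavage site, and it spans at most ``max_missed``
    internal cleavage sites.  Cleavage: after K/R, not before P.
    Independent of the implementation's segment-joining approach.
    """

    def cuts_after(i: int) -> bool:
        return (
            sequence[i] in "KR"
            and i + 1 < len(sequence)
            and sequence[i + 1] != "P"
        )

    n = len(sequence)
    out = set()
    for i in range(n):
        if not (i == 0 or cuts_after(i - 1)):
            continue
        for j in range(i, n):
            if not (j == n - 1 or cuts_after(j)):
                continue
            internal = sum(1 for k in range(i, j) if cuts_after(k))
            if internal <= max_missed:
                out.add((i + 1, j + 1, sequence[i : j + 1]))
    return out


def oracle_uniqueness(
    peptide: str, proteome: list[ProteinRecord], max_missed: int = 2
) -> int:
    """Count proteins whose enumerated tryptic substrings include the peptide."""
    count = 0
    for protein in proteome:
        seqs = {s for _i, _j, s in oracle_digest(protein.sequence, max_missed)}
        if peptide in seqs:
            count += 1
    return count


def random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: 12 controls + 4 patients, fixed seed."""
    return make_cohort(ScenarioConfig())


@pytest.fixture(scope="session")
def default_result(default_cohort):
    ds = default_cohort
    return quantify_cohort(ds.panel, ds.runs, ds.groups)
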