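"""Built-in chemical specifications and experimental stability constants.

The package ships everything it needs: atomic parameters for the five
bivalent first-row transition metals of the Irving-Williams series
(Mn, Fe, Co, Ni, Cu), heavy-atom topologies of the four aliphatic
alpha-amino-acid ligands (glycine, alanine, valine, leucine), and the
table of experimental log K1 / log beta2 values compiled from the
potentiometric literature (25 degC, I = 0.01 mol/L or extrapolated to
zero ionic strength; the three Fe constants were measured at 20 degC).

Missing measurements are represented as ``None``, never as zero or a
sentinel.  Zn belongs to the Irving-Williams order but no constants are
available for it under comparable conditions, so it is not included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MetalSpec",
    "AminoAcidSpec",
    "StabilityRecord",
    "METALS",
    "AMINO_ACIDS",
    "MODEL_METALS",
    "LIGANDS",
    "metal_spec",
    "amino_acid_spec",
    "load_experimental_table",
    "get_record",
    "records_to_frame",
    "write_records_csv",
    "read_records_csv",
]


@dataclass(frozen=True)
class MetalSpec:
    """A supported metal: element symbol, atomic number and valence-electron count.

    ``Zv`` is the d+s electron count of the neutral atom (Mn 7 ... Cu 11);
    the 2+ oxidation state is deliberately not subtracted, because the
    connectivity-index weighting uses neutral-atom electron counts.
    """

    symbol: str
    Z: int
    Zv: int

    def __post_init__(self) -> None:
        if not (self.Z > self.Zv >= 1):
            raise ValueError(f"invalid metal parameters for {self.symbol}")
        if self.Z - self.Zv - 1 <= 0:
            raise ValueError(f"nonpositive delta denominator for {self.symbol}")


@dataclass(frozen=True)
class AminoAcidSpec:
    """Heavy-atom topology of an alpha-amino-acid ligand.

    The backbone (N, C-alpha, carboxyl C, coordinating carboxylate O,
    pendant carbonyl O) is identical for all four acids; they differ only
    in the side chain attached to C-alpha.  ``side_chain`` lists the
    side-chain carbons as ``(name, n_hydrogens, parent_name)`` triples,
    where the parent is ``"CA"`` or an earlier side-chain carbon.
    """

    name: str
    ca_nH: int
    side_chain: tuple[tuple[str, int, str], ...]

    @property
    def n_heavy_atoms(self) -> int:
        """Heavy atoms of the bound ligand (backbone 5 + side chain)."""
        return 5 + len(self.side_chain)


@dataclass(frozen=True)
class StabilityRecord:
    """One experimental entry: metal, ligand, log K1 and log beta2 (log units).

    Either constant may be ``None`` when no measurement under comparable
    conditions exists.
    """

    metal: str
    ligand: str
    logK1: float | None
    logB2: float | None


METALS: dict[str, MetalSpec] = {
    "Mn": MetalSpec("Mn", 25, 7),
    "Fe": MetalSpec("Fe", 26, 8),
    "Co": MetalSpec("Co", 27, 9),
    "Ni": MetalSpec("Ni", 28, 10),
    "Cu": MetalSpec("Cu", 29, 11),
}

#: Metals entering the simultaneous regression model. Cu deviates strongly
#: from the quadratic trend of the other four and is excluded from fitting.
MODEL_METALS: tuple[str, ...] = ("Mn", "Fe", "Co", "Ni")

AMINO_ACIDS: dict[str, AminoAcidSpec] = {
    "glycine": AminoAcidSpec("glycine", ca_nH=2, side_chain=()),
    "alanine": AminoAcidSpec(
        "alanine", ca_nH=1, side_chain=(("CB", 3, "CA"),)
    ),
    "valine": AminoAcidSpec(
        "valine",
        ca_nH=1,
        side_chain=(("CB", 1, "CA"), ("CG1", 3, "CB"), ("CG2", 3, "CB")),
    ),
    "leucine": AminoAcidSpec(
        "leucine",
        ca_nH=1,
        side_chain=(
            ("CB", 2, "CA"),
            ("CG", 1, "CB"),
            ("CD1", 3, "CG"),
            ("CD2", 3, "CG"),
        ),
    ),
}

#: Ligands in order of increasing size (and increasing chi).
LIGANDS: tuple[str, ...] = ("glycine", "alanine", "valine", "leucine")


class UnsupportedElementError(KeyError):
    """Raised when a metal or ligand outside the supported set is requested."""


def metal_spec(symbol: str) -> MetalSpec:
    """Return the :class:`MetalSpec` for a supported metal symbol."""
    try:
        return METALS[symbol]
    except KeyError:
        raise UnsupportedElementError(
            f"unsupported metal {symbol!r}; supported: {sorted(METALS)}"
        ) from None


def amino_acid_spec(name: str) -> AminoAcidSpec:
    """Return the :class:`AminoAcidSpec` for a supported ligand name."""
    try:
        return AMINO_ACIDS[name.lower()]
    except KeyError:
        raise UnsupportedElementError(
            f"unsupported ligand {name!r}; supported: {sorted(AMINO_ACIDS)}"
        ) from None


def _records_from_frame(df: pd.DataFrame) -> list[StabilityRecord]:
    records = []
    for row in df.itertuples(index=False):
        k1 = None if pd.isna(row.logK1) else float(row.logK1)
        b2 = None if pd.isna(row.logB2) else float(row.logB2)
        records.append(StabilityRecord(str(row.metal), str(row.ligand), k1, b2))
    return records


def load_experimental_table() -> list[StabilityRecord]:
    """Load the 18 experimental stability records shipped with the package."""
    with resources.files("chelstab.data").joinpath(
        "experimental_constants.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    return _records_from_frame(df)


def get_record(
    records: Iterable[StabilityRecord], metal: str, ligand: str
) -> StabilityRecord:
    """Look up a (metal, ligand) pair; unmeasured pairs give an all-absent record."""
    for rec in records:
        if rec.metal == metal and rec.ligand == ligand:
            return rec
    return StabilityRecord(metal, ligand, None, None)


def records_to_frame(records: Sequence[StabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metal": [r.metal for r in records],
            "ligand": [r.ligand for r in records],
            "logK1": [math.nan if r.logK1 is None else r.logK1 for r in records],
            "logB2": [math.nan if r.logB2 is None else r.logB2 for r in records],
        }
    )


def write_records_csv(records: Sequence[StabilityRecord], path: str | Path) -> None:
    """Write records as CSV; absent constants become empty cells."""
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[StabilityRecord]:
    """Read a records CSV written by :func:`write_records_csv`."""
    return _records_from_frame(pd.read_csv(path))
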