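"""The published adduct observation dataset and the per-dG <-> pmol/mm^3 conversion.

The packaged table carries every measured adduct concentration used or carried
by the model: DG monoadducts from a single-exposure study (Lu2011) and a 28-day
time-course study (Yu2015), deoxyguanosine-specific crosslinks (DPC, fixtures
only) from Moeller2011 and Leng2019, and whole-DNA DNA-protein crosslinks
(DPX) from the chronic Casanova studies. Values are pmol adduct per mm^3
tissue; the DG and DPC studies originally reported adducts per 10^7 (DG) or
10^8 (DPC) deoxyguanosine and were converted with the constants below.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

AVOGADRO = 6.022e23

STUDIES = ("Lu2011", "Yu2015", "Moeller2011", "Leng2019", "Casanova1989", "Casanova1994")
ADDUCT_SPECIES = ("endoDG", "exogDG", "endoDPC", "exogDPC", "exogDPX")

#: Reported limit of detection for exogenous DG adducts (pmol/mm^3).
LOD_EXOG_DG = 5.26e-7


@dataclass(frozen=True)
class AdductObservation:
    """One measured adduct concentration — the calibration currency."""

    study: str
    ppm: float
    time_h: float  # from protocol origin; NaN for unexposed controls
    species: str
    value: float  # pmol/mm^3; NaN when below_LOD
    below_LOD: bool = False

    def __post_init__(self) -> None:
        # study is free-form so synthetic datasets can carry their own labels;
        # the loader's filters still reject unknown study names.
        if self.species not in ADDUCT_SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if not self.below_LOD and not self.value >= 0:
            raise ValueError("observation value must be non-negative unless below LOD")


@dataclass(frozen=True)
class ConversionConstants:
    """Constants of the adducts-per-deoxyguanosine to pmol/mm^3 conversion.

    ``genome_bp`` is the measured rat haploid genome size, ``g_fraction`` the
    G:C fraction of base pairs, ``cell_volume_mm3`` an epidermal-cell volume
    (no rat nasal value was available), ``ploidy`` the genome copies per
    nucleus (explicit because the published conversion's ploidy convention is
    the one auditable ambiguity), and ``per_dG_basis`` the denominator of the
    reported unit (10^7 dG for monoadduct data, 10^8 for DPC data).
    """

    genome_bp: float = 3.024e9
    g_fraction: float = 0.41
    cell_volume_mm3: float = 7.5e-7
    ploidy: float = 2.0
    per_dG_basis: float = 1e7

    def __post_init__(self) -> None:
        for name in ("genome_bp", "g_fraction", "cell_volume_mm3", "ploidy", "per_dG_basis"):
            if not getattr(self, name) > 0:
                raise ValueError(f"conversion constant {name} must be positive")

    @property
    def dG_per_cell(self) -> float:
        """Deoxyguanosine residues per nucleus."""
        return self.ploidy * self.genome_bp * self.g_fraction


def per_dG_to_conc(x: float, c: ConversionConstants = ConversionConstants()) -> float:
    """Convert adducts per ``per_dG_basis`` deoxyguanosine to pmol/mm^3 tissue.

    Adducts per cell = x * dG_per_cell / per_dG_basis; divide by cell volume
    for adducts/mm^3, by Avogadro's number for mol/mm^3, and scale to pmol.
    With the defaults, 1 adduct per 10^7 dG is about 5.49e-4 pmol/mm^3.
    """
    if x < 0:
        raise ValueError("adduct load must be non-negative")
    adducts_per_cell = x * c.dG_per_cell / c.per_dG_basis
    return adducts_per_cell / c.cell_volume_mm3 / AVOGADRO * 1e12


def conc_to_per_dG(v: float, c: ConversionConstants = ConversionConstants()) -> float:
    """Exact inverse of :func:`per_dG_to_conc`."""
    if v < 0:
        raise ValueError("concentration must be non-negative")
    adducts_per_cell = v * 1e12 ** -1 * AVOGADRO * c.cell_volume_mm3
    return adducts_per_cell * c.per_dG_basis / c.dG_per_cell


def _read_table() -> pd.DataFrame:
    resource = importlib.resources.files("formadose").joinpath("data/observations.csv")
    with resource.open() as fh:
        df = pd.read_csv(
            fh,
            dtype={"study": str, "species": str},
            converters={
                # tolerate a unicode minus sign in scientific notation
                "value_pmol_mm3": lambda s: float(s.replace("−", "-")) if s else float("nan"),
            },
        )
    df["below_lod"] = df["below_lod"].astype(str).str.lower().eq("true")
    return df


def load_table() -> pd.DataFrame:
    """The packaged observation table as a tidy DataFrame (one species per row)."""
    return _read_table()


def load_observations(
    study: str | Sequence[str] | None = None,
    species: str | Sequence[str] | None = None,
    predicate: Callable[[AdductObservation], bool] | None = None,
) -> list[AdductObservation]:
    """Load the packaged dataset, optionally filtered by study and/or species.

    Unknown study or species names in the filter raise ``ValueError``.
    """
    def as_tuple(x: str | Sequence[str] | None, valid: tuple[str, ...], what: str):
        if x is None:
            return valid
        items = (x,) if isinstance(x, str) else tuple(x)
        for item in items:
            if item not in valid:
                raise ValueError(f"unknown {what} {item!r}")
        return items

    studies = as_tuple(study, STUDIES, "study")
    specs = as_tuple(species, ADDUCT_SPECIES, "species")
    obs = [
        AdductObservation(
            study=row.study,
            ppm=float(row.ppm),
            time_h=float(row.time_h) if pd.notna(row.time_h) else float("nan"),
            species=row.species,
            value=float(row.value_pmol_mm3) if pd.notna(row.value_pmol_mm3) else float("nan"),
            below_LOD=bool(row.below_lod),
        )
        for row in _read_table().itertuples()
        if row.study in studies and row.species in specs
    ]
    if predicate is not None:
        obs = [o for o in obs if predicate(o)]
    return obs
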