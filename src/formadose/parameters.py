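"""Kinetic parameters and CFD site-flux constants for the nasal-mucosa dosimetry model.

All concentrations are pmol/mm^3 (numerically equal to uM), all times are hours.
The defaults are the published calibrated parameter set for the F344 rat nasal
mucosa; the two site fluxes are the CFD-predicted wall mass-transfer rates at
1 ppm inhaled formaldehyde for the DPX ("high tumor") and DG sampling sites.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


class InvalidParameterError(ValueError):
    """A kinetic or geometric parameter violates its physical constraints."""


class ConfigError(ValueError):
    """A parameter configuration file is malformed or names unknown keys."""


_EC_MODES = ("off", "zero_order", "saturable")


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants, capacities and initial concentrations of the mucosal model.

    Parameters
    ----------
    kp : float
        Zero-order endogenous formaldehyde production rate (pmol/mm^3/h).
    k21 : float
        First-order formaldehyde loss constant (1/h).
    k23 : float
        Second-order formaldehyde + GSH association constant (mm^3/pmol/h).
    k32 : float
        First-order dissociation constant of the formaldehyde-GSH complex (1/h).
    kDNA_DG : float
        First-order deoxyguanosine monoadduct formation constant (1/h).
    kDNA_DPX : float
        First-order DNA-protein crosslink formation constant (1/h).
    krep_DG : float
        First-order DG-adduct repair/loss constant (1/h).
    krep_DPX : float
        First-order DPX repair/loss constant (1/h).
    Vmax : float
        Maximum formaldehyde-dehydrogenase oxidation rate of the GSH complex
        (pmol/mm^3/h).
    Km : float
        Affinity constant of the complex for the enzyme (pmol/mm^3).
    thick : float
        Mucosal thickness (mm); converts wall flux into a volumetric uptake.
    endoF_init, GSH_init, endoF_GSH_init, endoDG_init, endoDPX_init : float
        Published approximate initial concentrations (pmol/mm^3). Multi-day
        simulations are insensitive to these; runs normally start from the
        endogenous steady state instead.
    ec_mode : str
        Extracellular-clearance variant: ``off`` (base model), ``zero_order``
        or ``saturable``.
    ec_rate : float
        Zero-order extracellular clearance rate (pmol/mm^3/h, ``zero_order``).
    ec_Vmax, ec_Km : float
        Saturable extracellular clearance parameters (``saturable``).
    """

    kp: float = 10835.0
    k21: float = 16.57
    k23: float = 0.35
    k32: float = 200.0
    kDNA_DG: float = 9.5183e-8
    kDNA_DPX: float = 1.8183e-4
    krep_DG: float = 0.0063
    krep_DPX: float = 0.39
    Vmax: float = 74156.0
    Km: float = 1935.0
    thick: float = 0.1138
    endoF_init: float = 20.0
    GSH_init: float = 4506.0
    endoF_GSH_init: float = 120.0
    endoDG_init: float = 7.42e-4
    endoDPX_init: float = 0.01
    ec_mode: str = "off"
    ec_rate: float = 2.02e3
    ec_Vmax: float = 0.0
    ec_Km: float = 1.0

    _POSITIVE = (
        "kp", "k21", "k23", "k32", "kDNA_DG", "kDNA_DPX",
        "krep_DG", "krep_DPX", "Vmax", "Km", "thick",
    )
    _NONNEGATIVE = (
        "endoF_init", "GSH_init", "endoF_GSH_init", "endoDG_init",
        "endoDPX_init", "ec_rate", "ec_Vmax",
    )

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        for name in self._NONNEGATIVE:
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.ec_mode not in _EC_MODES:
            raise InvalidParameterError(
                f"ec_mode must be one of {_EC_MODES}, got {self.ec_mode!r}"
            )
        if self.ec_mode == "saturable" and not (self.ec_Vmax > 0 and self.ec_Km > 0):
            raise InvalidParameterError("saturable clearance requires ec_Vmax, ec_Km > 0")

    def replace(self, **changes: object) -> "KineticParameters":
        """Return a copy with the named fields changed."""
        return dataclasses.replace(self, **changes)

    @property
    def total_glutathione(self) -> float:
        """Conserved glutathione-moiety pool (free GSH + both complexes), pmol/mm^3."""
        return self.GSH_init + self.endoF_GSH_init

    def as_dict(self) -> dict[str, object]:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Short provenance digest of the parameter values."""
        body = ",".join(f"{k}={v!r}" for k, v in sorted(self.as_dict().items()))
        return hashlib.sha256(body.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class SiteFlux:
    """CFD-predicted wall mass flux of inhaled formaldehyde at a sampling site.

    ``flux_per_ppm`` is the breath-averaged flux at 1 ppm inhaled concentration
    (pmol/mm^2/h per ppm); flux is assumed linear in the inhaled concentration.
    ``surface_area_mm2`` is informational (both sides of the nose).
    """

    site_label: str
    flux_per_ppm: float
    surface_area_mm2: float | None = None

    def __post_init__(self) -> None:
        if not self.flux_per_ppm > 0:
            raise InvalidParameterError("flux_per_ppm must be strictly positive")


#: High-tumor-region site where DNA-protein crosslinks were measured.
DPX_SITE = SiteFlux("DPX_high_tumor", flux_per_ppm=800.3, surface_area_mm2=171.6)
#: Larger respiratory-epithelium site where DG monoadducts were measured.
DG_SITE = SiteFlux("DG_site", flux_per_ppm=776.6, surface_area_mm2=419.9)

SITES = {"dpx": DPX_SITE, "dg": DG_SITE}

_UNITS = {
    "kp": "pmol/mm^3/h",
    "k21": "1/h",
    "k23": "mm^3/pmol/h",
    "k32": "1/h",
    "kDNA_DG": "1/h",
    "kDNA_DPX": "1/h",
    "krep_DG": "1/h",
    "krep_DPX": "1/h",
    "Vmax": "pmol/mm^3/h",
    "Km": "pmol/mm^3",
    "thick": "mm",
    "endoF_init": "pmol/mm^3",
    "GSH_init": "pmol/mm^3",
    "endoF_GSH_init": "pmol/mm^3",
    "endoDG_init": "pmol/mm^3",
    "endoDPX_init": "pmol/mm^3",
    "ec_mode": "off|zero_order|saturable",
    "ec_rate": "pmol/mm^3/h",
    "ec_Vmax": "pmol/mm^3/h",
    "ec_Km": "pmol/mm^3",
}

_FIELD_NAMES = tuple(f.name for f in dataclasses.fields(KineticParameters))


def write_params(params: KineticParameters, path: str | Path) -> None:
    """Write parameters as a flat ``key = value`` file (units in comments).

    Float values are written with ``repr`` so a write/read round-trip is
    bit-exact.
    """
    lines = ["# formadose kinetic parameter configuration"]
    for name in _FIELD_NAMES:
        value = getattr(params, name)
        text = value if isinstance(value, str) else repr(value)
        lines.append(f"{name} = {text}  # {_UNITS[name]}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_params(pairs: Iterable[tuple[str, str]], *, source: str = "<config>") -> KineticParameters:
    """Build parameters from (key, raw-value) pairs; missing keys take defaults."""
    overrides: dict[str, object] = {}
    for key, raw in pairs:
        if key not in _FIELD_NAMES:
            raise ConfigError(f"{source}: unknown parameter key {key!r}")
        if key == "ec_mode":
            overrides[key] = raw
        else:
            try:
                overrides[key] = float(raw)
            except ValueError as exc:
                raise ConfigError(f"{source}: cannot parse {key} = {raw!r}") from exc
    return KineticParameters(**overrides)  # type: ignore[arg-type]


def read_params(path: str | Path) -> KineticParameters:
    """Read a flat key-value parameter file; missing keys take the defaults.

    Unknown keys are errors (no silent typos). Lines starting with ``#`` and
    blank lines are ignored; inline ``#`` comments are stripped.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        if "=" not in text:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, raw = text.partition("=")
        pairs.append((key.strip(), raw.strip()))
    return parse_params(pairs, source=str(path))
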