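"""Library of 35 yield-sensitive multispectral vegetation indices.

All indices are arithmetic combinations of five band reflectances
(blue, green, red, red-edge, NIR) as measured by a typical UAV
multispectral sensor (e.g. MicaSense RedEdge-MX: B 475 nm, G 560 nm,
R 668 nm, RE 717 nm, NIR 840 nm).

Two formula dialects are provided:

``"as_printed"`` (default)
    The formulas exactly as tabulated in the source index compilation,
    including forms that deviate from the wider remote-sensing
    literature (e.g. TVI without the square root, NLI with 0.1-scale
    linear coefficients instead of a squared NIR term, literal ATSAVI
    constants).  This dialect exists so that results are reproducible
    against that compilation.

``"corrected"``
    Standard literature forms substituted only where the printed form
    is a known typographic variant (TVI, CCCI, NLI, MNLI, ATSAVI).
    Every substitution is listed in :data:`CORRECTED_SUBSTITUTIONS`.

Zero denominators yield missing values (NaN), never clamped numbers:
silently clamping an undefined ratio would corrupt downstream feature
rankings.  Index names are the exact abbreviations of the compilation
and matching is case-sensitive.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BandReflectance",
    "VITable",
    "BAND_NAMES",
    "DIALECTS",
    "CORRECTED_SUBSTITUTIONS",
    "UnknownIndexError",
    "list_indices",
    "index_order",
    "compute_index",
    "compute_all",
    "validate_bands",
]

BAND_NAMES = ("blue", "green", "red", "red_edge", "nir")

DIALECTS = ("as_printed", "corrected")


class UnknownIndexError(KeyError):
    """Raised when an index name is not one of the 35 library names."""


@dataclasses.dataclass(frozen=True)
class BandReflectance:
    """Five-band surface reflectance for one plot (unitless, nominally in [0, 1])."""

    blue: float
    green: float
    red: float
    red_edge: float
    nir: float

    def __post_init__(self) -> None:
        for name in BAND_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"band {name!r} must be finite, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in BAND_NAMES}


def validate_bands(bands: Mapping[str, float] | BandReflectance) -> list[str]:
    """Check reflectances against the nominal [0, 1] range.

    Returns a list of warning messages (one per out-of-range band) and
    emits each as a :class:`UserWarning`.  Out-of-range values are
    allowed — radiometric pipelines occasionally overshoot — so this
    warns rather than fails.
    """
    if isinstance(bands, BandReflectance):
        bands = bands.as_dict()
    messages = []
    for name in BAND_NAMES:
        v = float(bands[name])
        if not 0.0 <= v <= 1.0:
            msg = f"reflectance {name}={v:g} outside nominal [0, 1]"
            messages.append(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)
    return messages


# ---------------------------------------------------------------------------
# Formula table.  Each entry maps an index abbreviation to a function of the
# five bands (vectorised; b, g, r, re, nir are floats or ndarrays).  Order is
# the canonical table order and is the tie-break order used everywhere else
# in the package.
# ---------------------------------------------------------------------------

_F: dict[str, Callable] = {
    "NDVI": lambda b, g, r, re, nir: (nir - r) / (nir + r),
    "NDRE": lambda b, g, r, re, nir: (nir - re) / (nir + re),
    "GNDVI": lambda b, g, r, re, nir: (nir - g) / (nir + g),
    # printed as (NIR−RE)/(NIR+RE)/(NIR−R)/(NIR+R): left-to-right division
    "CCCI": lambda b, g, r, re, nir: ((nir - re) / (nir + re)) / (nir - r) / (nir + r),
    "GRVI": lambda b, g, r, re, nir: nir / g,
    "RGR": lambda b, g, r, re, nir: r / g,
    "RRI1": lambda b, g, r, re, nir: nir / re,
    "RRI2": lambda b, g, r, re, nir: re / r,
    # literal printed constants, including the trailing 1.22 in the numerator
    # and the 1.222 in the denominator
    "ATSAVI": lambda b, g, r, re, nir: 1.22 * (nir - 1.22 * r - 1.22)
    / (1.22 * nir + r - 1.22 * 0.03 + 0.08 * (1 + 1.222)),
    "CIg": lambda b, g, r, re, nir: nir / g - 1.0,
    "CIre": lambda b, g, r, re, nir: nir / re - 1.0,
    "IVI": lambda b, g, r, re, nir: (nir - 0.03) / (1.22 * r),
    "DVI": lambda b, g, r, re, nir: nir - r,
    "WDVI": lambda b, g, r, re, nir: nir - 1.22 * r,
    "TVI": lambda b, g, r, re, nir: (nir - r) / (nir + r) + 0.5,
    "WDRVI": lambda b, g, r, re, nir: (0.1 * nir - r) / (0.1 * nir + r),
    "TNDVI": lambda b, g, r, re, nir: (nir - r) / (nir + r + 0.5),
    "SAVI": lambda b, g, r, re, nir: 1.5 * (nir - r) / (nir + r + 0.16),
    "GDVI": lambda b, g, r, re, nir: nir - g,
    "GSAVI": lambda b, g, r, re, nir: 1.5 * (nir - g) / (nir + g + 0.5),
    "NormG": lambda b, g, r, re, nir: g / (nir + r + g),
    "NormNIR": lambda b, g, r, re, nir: nir / (r + g + nir),
    "NormR": lambda b, g, r, re, nir: r / (r + g + nir),
    "NGRDI": lambda b, g, r, re, nir: (g - r) / (g + r),
    "RI": lambda b, g, r, re, nir: (r - g) / (r + g),
    "CVI": lambda b, g, r, re, nir: nir * r / (g * g),
    "RVI": lambda b, g, r, re, nir: nir / r,
    "NLI": lambda b, g, r, re, nir: (0.12 * nir - r) / (0.12 * nir + r),
    "MNLI": lambda b, g, r, re, nir: (1.5 * nir**2 - 1.5 * g) / (nir**2 + r + 0.5),
    "OSAVI": lambda b, g, r, re, nir: (nir - r) / (nir + r + 0.16),
    "TCARI": lambda b, g, r, re, nir: 3.0 * ((re - r) - 0.2 * (re - g) * (re / r)),
    "MCARI": lambda b, g, r, re, nir: ((re - r) - 0.2 * (re - g)) * (re / r),
    "GCI": lambda b, g, r, re, nir: nir / g - 1.0,
    "RECI": lambda b, g, r, re, nir: nir / re - 1.0,
    "MRVI": lambda b, g, r, re, nir: (nir / r - 1.0) / (nir / r + 1.0),
}

#: Standard literature forms substituted under dialect="corrected"; every
#: entry here replaces the as-printed formula of the same name.
CORRECTED_SUBSTITUTIONS: dict[str, Callable] = {
    "TVI": lambda b, g, r, re, nir: np.sqrt((nir - r) / (nir + r) + 0.5),
    "CCCI": lambda b, g, r, re, nir: ((nir - re) / (nir + re))
    / ((nir - r) / (nir + r)),
    "NLI": lambda b, g, r, re, nir: (nir**2 - r) / (nir**2 + r),
    "MNLI": lambda b, g, r, re, nir: 1.5 * (nir**2 - r) / (nir**2 + r + 0.5),
    "ATSAVI": lambda b, g, r, re, nir: 1.22 * (nir - 1.22 * r - 0.03)
    / (1.22 * nir + r - 1.22 * 0.03 + 0.08 * (1 + 1.22**2)),
}

_NAMES: tuple[str, ...] = tuple(_F)
_ORDER: dict[str, int] = {name: i for i, name in enumerate(_NAMES)}

assert len(_NAMES) == 35


def list_indices() -> list[str]:
    """Return the 35 index names in canonical table order (stable)."""
    return list(_NAMES)


def index_order(name: str) -> int:
    """Position of *name* in the canonical table order (tie-break key)."""
    if name not in _ORDER:
        raise UnknownIndexError(name)
    return _ORDER[name]


def _formula(name: str, dialect: str) -> Callable:
    if name not in _F:
        raise UnknownIndexError(name)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "corrected" and name in CORRECTED_SUBSTITUTIONS:
        return CORRECTED_SUBSTITUTIONS[name]
    return _F[name]


def _evaluate(fn: Callable, b, g, r, re, nir):
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = fn(b, g, r, re, nir)
    # undefined values (zero denominators, sqrt of negative) -> NaN
    return np.where(np.isfinite(out), out, np.nan)


def compute_index(
    name: str,
    bands: Mapping[str, float] | BandReflectance,
    dialect: str = "as_printed",
) -> float:
    """Evaluate one named index at the given band reflectances.

    Returns NaN when the formula is undefined at the input (exact zero
    denominator).  Unknown names raise :class:`UnknownIndexError`.
    """
    if isinstance(bands, BandReflectance):
        bands = bands.as_dict()
    fn = _formula(name, dialect)
    # numpy scalars so exact zero denominators yield inf/nan, not an exception
    args = [np.float64(bands[k]) for k in BAND_NAMES]
    return float(_evaluate(fn, *args))


@dataclasses.dataclass
class VITable:
    """Per-plot values of the 35 indices, plus the dialect that produced them.

    ``data`` is indexed by plot_id with exactly the 35 index columns in
    canonical order; undefined formula evaluations are stored as NaN.
    """

    data: pd.DataFrame
    dialect: str = "as_printed"

    def __post_init__(self) -> None:
        expected = list(_NAMES)
        got = list(self.data.columns)
        if got != expected:
            raise ValueError(
                f"VITable must have exactly the 35 index columns in order; got {got}"
            )

    @property
    def index_names(self) -> list[str]:
        return list(self.data.columns)

    def missing_report(self) -> pd.Series:
        """Count of missing (undefined) values per index."""
        return self.data.isna().sum()

    def rows_with_missing(self) -> list:
        """plot_ids of rows where any index is undefined."""
        return list(self.data.index[self.data.isna().any(axis=1)])

    def to_csv(self, path: str | Path) -> None:
        """Write the table; the dialect is recorded in a JSON sidecar."""
        path = Path(path)
        self.data.to_csv(path, index_label="plot_id")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps({"dialect": self.dialect}, indent=2) + "\n")

    @classmethod
    def read_csv(cls, path: str | Path) -> "VITable":
        path = Path(path)
        data = pd.read_csv(path, index_col="plot_id")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        dialect = "as_printed"
        if sidecar.exists():
            dialect = json.loads(sidecar.read_text()).get("dialect", dialect)
        return cls(data=data, dialect=dialect)


def compute_all(plot_table: pd.DataFrame, dialect: str = "as_printed") -> VITable:
    """Compute all 35 indices for every row of a plot table.

    *plot_table* must carry the five band columns; a ``plot_id`` column,
    if present, becomes the output index.  Deterministic: equal inputs
    give bit-identical outputs.
    """
    missing_cols = [c for c in BAND_NAMES if c not in plot_table.columns]
    if missing_cols:
        raise KeyError(f"plot table is missing band column(s): {missing_cols}")
    bands = [plot_table[c].to_numpy(dtype=float) for c in BAND_NAMES]
    cols = {name: _evaluate(_formula(name, dialect), *bands) for name in _NAMES}
    index = (
        pd.Index(plot_table["plot_id"], name="plot_id")
        if "plot_id" in plot_table.columns
        else plot_table.index
    )
    return VITable(data=pd.DataFrame(cols, index=index), dialect=dialect)
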