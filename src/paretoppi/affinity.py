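"""Binding-affinity curation and the normalized regression endpoint.

Dissociation/inhibition constants are converted to Gibbs free energy with
dG = RT ln(K) at the experimental temperature (300 K when unstated), and
the retained dG values are min-max normalized to [0, 1] for regression;
the scaler inverts predictions back to kJ/mol.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interactions import canonical_pair

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314
DEFAULT_TEMPERATURE_K = 300.0

#: Molar-unit multipliers for Kd/Ki values.
_UNIT_SCALE = {
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9,
    "pM": 1e-12, "fM": 1e-15,
}
_DG_UNITS = {"kJ/mol": 1.0, "kcal/mol": 4.184}

_RANGE_RE = re.compile(r"[~><]|\d\s*[-–—]\s*\d|\bto\b")


class DegenerateScaleError(ValueError):
    """All endpoint values are equal; no [0,1] scale exists."""


def delta_g_from_k(k: float, temperature_K: float | None = None) -> float:
    """dG = RT ln(K), in kJ/mol. Strictly increasing in K."""
    if k <= 0:
        raise ValueError(f"equilibrium constant must be positive, got {k}")
    t = DEFAULT_TEMPERATURE_K if temperature_K is None else float(temperature_K)
    if t <= 0:
        raise ValueError(f"temperature must be positive, got {t}")
    return R_GAS * t * math.log(k) / 1000.0


def k_from_delta_g(delta_g_kj: float, temperature_K: float | None = None) -> float:
    """Inverse of :func:`delta_g_from_k`."""
    t = DEFAULT_TEMPERATURE_K if temperature_K is None else float(temperature_K)
    return math.exp(delta_g_kj * 1000.0 / (R_GAS * t))


@dataclass(frozen=True)
class AffinityRecord:
    id_a: str
    id_b: str
    measure: str  # Kd | Ki | dG
    value: float  # M for Kd/Ki, kJ/mol for dG
    temperature_K: float | None
    delta_g_kj: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


def _parse_value(raw) -> float | None:
    """Parse an exact numeric value; ranges/inequalities are imprecise."""
    if isinstance(raw, (int, float)):
        return None if isinstance(raw, float) and math.isnan(raw) else float(raw)
    s = str(raw).strip()
    if _RANGE_RE.search(s):
        return None
    try:
        return float(s)
    except ValueError:
        return None


def curate(
    raw: pd.DataFrame,
    taxon: int = 9606,
    stoichiometry: str = "dimer",
) -> tuple[list[AffinityRecord], list[dict]]:
    """Apply the affinity curation cascade to a raw measurement table.

    Expects columns id_a, id_b, measure, value, unit, temperature_K, taxon,
    stoichiometry. Keeps human, dimeric, exact-valued records measured as
    Kd, Ki or dG; collapses duplicate unordered pairs to the first
    occurrence. Returns the retained records plus a rejection report with a
    reason code per dropped row.
    """
    kept: list[AffinityRecord] = []
    rejected: list[dict] = []
    seen_pairs: set[tuple[str, str]] = set()
    for i, row in raw.iterrows():
        def reject(reason: str) -> None:
            rejected.append({"row": int(i), "id_a": row["id_a"], "id_b": row["id_b"],
                             "reason": reason})

        if int(row["taxon"]) != taxon:
            reject("taxon")
            continue
        if str(row["stoichiometry"]).strip().lower() != stoichiometry:
            reject("stoichiometry")
            continue
        measure = str(row["measure"]).strip()
        unit = str(row["unit"]).strip()
        if measure in ("Kd", "Ki"):
            if unit not in _UNIT_SCALE:
                reject("unit")
                continue
        elif measure == "dG":
            if unit not in _DG_UNITS:
                reject("unit")
                continue
        else:
            reject("unit")
            continue
        value = _parse_value(row["value"])
        if value is None:
            reject("imprecise")
            continue
        temp = row.get("temperature_K")
        temp = None if temp is None or (isinstance(temp, float) and math.isnan(temp)) else float(temp)
        if measure == "dG":
            dg = value * _DG_UNITS[unit]
        else:
            molar = value * _UNIT_SCALE[unit]
            if molar <= 0:
                reject("imprecise")
                continue
            dg = delta_g_from_k(molar, temp)
            value = molar
        pair = canonical_pair(str(row["id_a"]), str(row["id_b"]))
        if pair in seen_pairs:
            reject("duplicate")
            continue
        seen_pairs.add(pair)
        kept.append(AffinityRecord(id_a=pair[0], id_b=pair[1], measure=measure,
                                   value=value, temperature_K=temp, delta_g_kj=dg))
    return kept, rejected


@dataclass(frozen=True)
class EndpointScaler:
    """Affine [g_min, g_max] -> [0, 1] map for the dG regression endpoint."""

    g_min: float
    g_max: float

    def __post_init__(self):
        if not self.g_min < self.g_max:
            raise DegenerateScaleError(
                f"g_min ({self.g_min}) must be < g_max ({self.g_max})"
            )

    @property
    def span(self) -> float:
        return self.g_max - self.g_min

    def transform(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.g_min) / self.span

    def inverse(self, endpoint01) -> np.ndarray:
        return np.asarray(endpoint01, dtype=float) * self.span + self.g_min

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"g_min": self.g_min, "g_max": self.g_max}, fh)

    @classmethod
    def from_json(cls, path) -> "EndpointScaler":
        with open(path) as fh:
            d = json.load(fh)
        return cls(g_min=d["g_min"], g_max=d["g_max"])


def normalize_endpoint(values) -> tuple[np.ndarray, EndpointScaler]:
    """Min-max normalize dG values; returns the scaler for inversion."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or np.ptp(arr) == 0:
        raise DegenerateScaleError("need at least 2 distinct dG values")
    scaler = EndpointScaler(g_min=float(arr.min()), g_max=float(arr.max()))
    return scaler.transform(arr), scaler


def denormalize(endpoint01, scaler: EndpointScaler) -> np.ndarray:
    return scaler.inverse(endpoint01)
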