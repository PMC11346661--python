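"""Wet-lab quantification equations for fruit pigments and the maturity index.

Chlorophyll a/b and total carotenoids follow the classic spectrophotometric
coefficient sets (absorbance read at 663, 645 and 480 nm on the crude
extract); lycopene uses the 503 nm single-wavelength assay on diluted juice.
All results are per gram of fresh tissue.

Negative concentrations are physically meaningless but can arise from noisy
absorbance readings; they are passed through with a ``UserWarning`` rather
than clamped, so upstream data problems stay visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "AbsorbanceRecord",
    "chlorophyll_a",
    "chlorophyll_b",
    "carotenoids",
    "lycopene",
    "maturity_index",
    "assay_table",
]


@dataclass(frozen=True)
class AbsorbanceRecord:
    """One spectrophotometer reading set for a single extract.

    Parameters
    ----------
    A663, A645, A480, A503 : float
        Absorbance (optical density) at the named wavelength, dimensionless.
    V : float
        Final volume of the chlorophyll/carotenoid extract in mL.
    W : float
        Fresh weight of the tissue sample in g.
    vol_sample : float
        Juice volume used in the lycopene assay, mL.
    dilution : float
        Dilution factor applied before reading A503 (>= 1).
    """

    A663: float = 0.0
    A645: float = 0.0
    A480: float = 0.0
    A503: float = 0.0
    V: float = 0.0
    W: float = 1.0
    vol_sample: float = 0.0
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError(f"fresh weight W must be > 0, got {self.W}")
        if self.V < 0:
            raise ValueError(f"extract volume V must be >= 0, got {self.V}")
        if self.dilution < 1:
            raise ValueError(f"dilution factor must be >= 1, got {self.dilution}")
        for name in ("A663", "A645", "A480", "A503"):
            if getattr(self, name) < 0:
                raise ValueError(f"absorbance {name} must be >= 0")


def _warn_if_negative(value: float, what: str) -> float:
    if value < 0:
        warnings.warn(
            f"{what} came out negative ({value:.4g}); check the absorbance "
            "readings — the value is reported unclamped",
            UserWarning,
            stacklevel=3,
        )
    return value


def chlorophyll_a(rec: AbsorbanceRecord) -> float:
    """Chlorophyll a concentration in mg per g tissue.

    ``[12.7 A663 - 2.69 A645] * V / (1000 W)``.
    """
    value = (12.7 * rec.A663 - 2.69 * rec.A645) * rec.V / (1000.0 * rec.W)
    return _warn_if_negative(value, "chlorophyll a")


def chlorophyll_b(rec: AbsorbanceRecord) -> float:
    """Chlorophyll b concentration in mg per g tissue.

    ``[22.9 A645 - 4.68 A663] * V / (1000 W)``.
    """
    value = (22.9 * rec.A645 - 4.68 * rec.A663) * rec.V / (1000.0 * rec.W)
    return _warn_if_negative(value, "chlorophyll b")


def carotenoids(rec: AbsorbanceRecord, variant: str = "standard") -> float:
    """Total carotenoids in mg per g fresh weight.

    variant="standard" uses the multiplicative correction
    ``[A480 + 0.114 A663 - 0.638 A645] * V / (1000 W)``, consistent with the
    Lichtenthaler-style coefficient convention and yielding physically
    plausible (non-negative) values for typical readings.

    variant="as_printed" evaluates the subtractive form
    ``[A480 + 0.114 A663 - (0.638 - A645)] * V / (1000 W)`` exactly as it is
    sometimes typeset; it is retained only for auditability and usually goes
    negative.
    """
    if variant == "standard":
        core = rec.A480 + 0.114 * rec.A663 - 0.638 * rec.A645
    elif variant == "as_printed":
        core = rec.A480 + 0.114 * rec.A663 - (0.638 - rec.A645)
    else:
        raise ValueError(f"unknown carotenoid variant {variant!r}")
    value = core * rec.V / (1000.0 * rec.W)
    return _warn_if_negative(value, "total carotenoids")


def lycopene(rec: AbsorbanceRecord) -> float:
    """Lycopene in µg per g fresh weight.

    ``3.121 * A503 * vol_sample * dilution / W``.
    """
    value = 3.121 * rec.A503 * rec.vol_sample * rec.dilution / rec.W
    return _warn_if_negative(value, "lycopene")


def maturity_index(tss: float, ta: float) -> float:
    """Maturity index: total soluble solids divided by titratable acidity.

    TSS is in °Brix (%), TA in % citric-acid equivalents; the ratio is
    dimensionless and rises as fruit ripens.
    """
    if ta <= 0:
        raise ValueError(f"titratable acidity must be > 0, got {ta}")
    return tss / ta


def assay_table(df, variant: str = "standard"):
    """Batch mode: append pigment columns to an absorbance table.

    ``df`` must carry the :class:`AbsorbanceRecord` fields as columns (missing
    ones default as in the dataclass). Returns a copy with ``Chl a``,
    ``Chl b``, ``Car`` and, where ``A503`` is present, ``Lycopene`` appended.
    """
    out = df.copy()
    fields = ("A663", "A645", "A480", "A503", "V", "W", "vol_sample", "dilution")
    records = [
        AbsorbanceRecord(**{f: float(row[f]) for f in fields if f in row})
        for row in out.to_dict("records")
    ]
    out["Chl a"] = [chlorophyll_a(r) for r in records]
    out["Chl b"] = [chlorophyll_b(r) for r in records]
    out["Car"] = [carotenoids(r, variant=variant) for r in records]
    if "A503" in df.columns:
        out["Lycopene"] = [lycopene(r) for r in records]
    return out
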