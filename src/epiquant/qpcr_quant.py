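"""Conversion of qPCR outputs to total 16S rRNA gene copies per cm².

The central quantity is the surface copy density

    N = n * C * V / (c * v * S)     [copies cm^-2]

where ``n`` is the number of 16S gene copies detected in the qPCR reaction,
``C`` the original DNA extract concentration (ng/uL), ``V`` the extract
volume (uL, default 50), ``c`` the normalised input concentration in the
reaction (ng/uL, default 0.5), ``v`` the input volume (uL, default 1.5) and
``S`` the swabbed surface (cm², default 50).  Extracts that were below the
normalisation target (C < c) enter the reaction undiluted; for those the
effective input concentration equals the extract concentration, so
N = n * V / (v * S).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from epiquant.io_model import SampleMetadata

DEFAULT_V = 50.0   # total extract volume, uL
DEFAULT_C_IN = 0.5  # normalised input DNA concentration, ng/uL
DEFAULT_V_IN = 1.5  # input volume per reaction, uL
DEFAULT_SURFACE = 50.0  # swabbed surface, cm^2

#: Default plausibility window for N (copies cm^-2).  Loads outside it are
#: flagged, never rejected: legitimate surface densities span orders of
#: magnitude (observed range on macroalgae is roughly 1e5 to 5e7).
DEFAULT_PLAUSIBILITY = (1e3, 1e9)


def copies_per_cm2(n, C, V=DEFAULT_V, c=DEFAULT_C_IN, v=DEFAULT_V_IN, S=DEFAULT_SURFACE):
    """Surface density of 16S gene copies, N = n*C*V / (c*v*S).

    Accepts scalars or numpy arrays; linear in ``n`` and in ``C``.
    """
    n = np.asarray(n, dtype=float)
    C = np.asarray(C, dtype=float)
    for name, value in (("c", c), ("v", v), ("S", S)):
        if np.any(np.asarray(value, dtype=float) <= 0):
            raise ValueError(f"invalid parameter {name}: must be > 0")
    for name, value in (("n", n), ("C", C), ("V", V)):
        if np.any(np.asarray(value, dtype=float) < 0):
            raise ValueError(f"invalid parameter {name}: must be >= 0")
    result = n * C * np.asarray(V, dtype=float) / (
        np.asarray(c, dtype=float) * np.asarray(v, dtype=float) * np.asarray(S, dtype=float)
    )
    if result.ndim == 0:
        return float(result)
    return result


@dataclasses.dataclass(frozen=True)
class StandardCurve:
    """qPCR standard curve: Cq = slope * log10(copies) + intercept.

    ``slope`` must be negative (more template, earlier quantification
    cycle).  Amplification efficiency is E = 10^(-1/slope) - 1; a perfect
    doubling per cycle gives slope = -1/log10(2) ~ -3.3219 and E = 1.
    """

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def copies_to_cq(self, copies) -> float:
        copies = np.asarray(copies, dtype=float)
        if np.any(copies <= 0):
            raise ValueError("copies must be > 0 to have a Cq")
        out = self.slope * np.log10(copies) + self.intercept
        return float(out) if out.ndim == 0 else out


def cq_to_copies(cq, curve: StandardCurve):
    """Copies in the reaction from a quantification cycle via the curve.

    copies = 10^((cq - intercept) / slope); monotonically decreasing in cq.
    """
    cq = np.asarray(cq, dtype=float)
    out = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return float(out) if out.ndim == 0 else out


def attach_loads(
    metadata: SampleMetadata,
    measurements: pd.DataFrame,
    *,
    curve: StandardCurve | None = None,
    V: float = DEFAULT_V,
    c: float = DEFAULT_C_IN,
    v: float = DEFAULT_V_IN,
    S: float = DEFAULT_SURFACE,
    plausibility: tuple[float, float] = DEFAULT_PLAUSIBILITY,
) -> pd.DataFrame:
    """Per-sample total loads N (copies cm^-2) with QC flags.

    ``measurements`` needs sample_id plus copies_in_reaction or cq (the
    latter requires ``curve``); replicate wells of one sample are averaged
    on the copies scale (the linear-scale quantity entering N), never on
    the Cq scale.  The extract concentration C comes from the measurement
    table's ``C`` column when present, else from metadata's dna_conc.

    Flags: "undiluted" when C < c (the extract was used as-is, so the
    effective input concentration is C and N = n*V/(v*S));
    "implausible_load" when N falls outside ``plausibility``.

    Raises ``KeyError`` naming the first sample lacking a measurement.
    """
    df = measurements.copy()
    if "copies_in_reaction" not in df.columns:
        if "cq" not in df.columns:
            raise ValueError("measurements require copies_in_reaction or cq")
        if curve is None:
            raise ValueError("cq-based measurements require a standard curve")
        df["copies_in_reaction"] = cq_to_copies(df["cq"].to_numpy(float), curve)
    per_sample = df.groupby("sample_id")["copies_in_reaction"].mean()
    if "C" in df.columns:
        conc = df.groupby("sample_id")["C"].first()
    else:
        conc = metadata.column("dna_conc")

    rows = []
    for sample_id in metadata.real_ids:
        if sample_id not in per_sample.index:
            raise KeyError(f"missing qPCR measurement for sample {sample_id!r}")
        n_copies = float(per_sample.loc[sample_id])
        C = float(conc.loc[sample_id])
        flags = []
        c_eff = c
        if C < c:
            # below the normalisation target: extract used undiluted
            c_eff = C
            flags.append("undiluted")
        N = copies_per_cm2(n_copies, C, V=V, c=c_eff, v=v, S=S)
        if not (plausibility[0] <= N <= plausibility[1]):
            flags.append("implausible_load")
        rows.append(
            {
                "sample_id": sample_id,
                "copies_in_reaction": n_copies,
                "C": C,
                "V": V,
                "c": c_eff,
                "v": v,
                "S": S,
                "N": N,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
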