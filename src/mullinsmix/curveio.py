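"""Stress-stretch curve container and CSV round-trip.

Curves are exchanged as plain CSV with columns ``stretch,stress,phase,cycle``
(phase/cycle optional; inferred from the monotonicity of the stretch when
absent).  Two metadata comment lines record the stress kind and unit, since
mixing Cauchy and engineering stress silently would corrupt fits:

    # stress_kind: engineering
    # unit: MPa
    stretch,stress,phase,cycle
    1.0,0.0,loading,1
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CurveParseError

PHASES = ("loading", "unloading", "reloading")
STRESS_KINDS = ("engineering", "cauchy")


@dataclass
class StressStretchCurve:
    """Ordered uniaxial stress-stretch samples with branch labels."""

    stretch: np.ndarray
    stress: np.ndarray
    phase: np.ndarray
    cycle: np.ndarray
    stress_kind: str = "engineering"
    unit: str = "MPa"

    def __post_init__(self):
        self.stretch = np.asarray(self.stretch, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        self.cycle = np.asarray(self.cycle, dtype=int)
        if not (self.stretch.size == self.stress.size == self.phase.size == self.cycle.size):
            raise ValueError("curve columns must have equal length")
        if np.any(self.stretch <= 0.0):
            raise ValueError("stretches must be positive")
        if self.stress_kind not in STRESS_KINDS:
            raise ValueError(f"stress_kind must be one of {STRESS_KINDS}")

    def __len__(self) -> int:
        return int(self.stretch.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stretch": self.stretch,
                "stress": self.stress,
                "phase": self.phase,
                "cycle": self.cycle,
            }
        )

    def branch(self, phase: str) -> "StressStretchCurve":
        """Sub-curve of one phase ('loading', 'unloading' or 'reloading')."""
        mask = self.phase == phase
        return StressStretchCurve(
            self.stretch[mask], self.stress[mask], self.phase[mask],
            self.cycle[mask], self.stress_kind, self.unit,
        )

    def has_phase(self, phase: str) -> bool:
        return bool(np.any(self.phase == phase))


def infer_phases(stretch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Label phases/cycles from stretch monotonicity alone.

    The first rising run (in |deformation|) is 'loading'; falling runs are
    'unloading'; later rising runs are 'reloading'.  Each unloading->rising
    transition starts a new cycle.
    """
    m = stretch**4 + 2.0 / stretch**2  # monotone proxy in deformation magnitude
    phases = np.empty(stretch.size, dtype=object)
    cycles = np.empty(stretch.size, dtype=int)
    phase, cycle, seen_unload = "loading", 1, False
    for i in range(stretch.size):
        if i > 0:
            if m[i] > m[i - 1]:
                new = "reloading" if seen_unload else "loading"
            elif m[i] < m[i - 1]:
                new = "unloading"
                seen_unload = True
            else:
                new = phase
            if phase == "unloading" and new != "unloading":
                cycle += 1
            phase = new
        phases[i] = phase
        cycles[i] = cycle
    return phases, cycles


def read_curve(path) -> StressStretchCurve:
    """Read a stress-stretch CSV, validating rows with line-numbered errors."""
    meta = {"stress_kind": "engineering", "unit": "MPa"}
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                if key.strip() in meta:
                    meta[key.strip()] = val.strip()
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # malformed CSV as a whole
        raise CurveParseError(f"{path}: cannot parse CSV: {exc}") from exc
    for col in ("stretch", "stress"):
        if col not in df.columns:
            raise CurveParseError(f"{path}: missing required column {col!r}")
    header_line = n_comment + 1
    for col in ("stretch", "stress"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
        if df[col].isna().any():
            bad = np.append(bad, np.flatnonzero(df[col].isna().to_numpy()))
        if bad.size:
            row = int(np.min(bad))
            raise CurveParseError(
                f"{path}: non-numeric {col} value {df[col].iloc[row]!r} "
                f"on line {header_line + 1 + row}"
            )
        df[col] = vals
    nonpos = np.flatnonzero(df["stretch"].to_numpy() <= 0.0)
    if nonpos.size:
        row = int(nonpos[0])
        raise CurveParseError(
            f"{path}: non-positive stretch {df['stretch'].iloc[row]} "
            f"on line {header_line + 1 + row}"
        )
    stretch = df["stretch"].to_numpy(dtype=float)
    stress = df["stress"].to_numpy(dtype=float)
    if "phase" in df.columns and df["phase"].notna().all():
        phase = df["phase"].astype(str).to_numpy(dtype=object)
        unknown = set(phase) - set(PHASES)
        if unknown:
            raise CurveParseError(f"{path}: unknown phase labels {sorted(unknown)}")
        if "cycle" in df.columns and df["cycle"].notna().all():
            cycle = df["cycle"].to_numpy(dtype=int)
        else:
            cycle = infer_phases(stretch)[1]
    else:
        phase, cycle = infer_phases(stretch)
    return StressStretchCurve(stretch, stress, phase, cycle,
                              meta["stress_kind"], meta["unit"])


def write_curve(curve: StressStretchCurve, path) -> None:
    """Write a curve as CSV; round-trips through :func:`read_curve` to 15+
    significant digits."""
    with open(path, "w") as fh:
        fh.write(f"# stress_kind: {curve.stress_kind}\n")
        fh.write(f"# unit: {curve.unit}\n")
        curve.to_frame().to_csv(fh, index=False, float_format="%.17g")
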