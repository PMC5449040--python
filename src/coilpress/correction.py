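"""Random-coil correction of protein pressure-shift tracks.

For each residue's measured shift-vs-pressure track the pipeline fits
the quadratic pressure model, subtracts the matching random-coil
reference coefficients, and scores the remaining pressure response:
``z_k = |dB_k| / sqrt(SE_obs^2 + SE_ref^2)``. Large z1 marks a residue
whose pressure response cannot be explained by the trivial random-coil
baseline. Absolute-shift (delta0) differences are reported but never
flagged — the correction concerns the pressure response only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fitting import FitError, PressureSeries, fit_quadratic
from .model import PressureCoefficients, predict_shift
from .reference import (
    ReferenceEntry,
    ReferenceLibrary,
    ReferenceLookupError,
    load_reference,
)

__all__ = [
    "PeakTrack",
    "CorrectionResult",
    "correct_tracks",
    "residual_curve",
    "read_tracks",
    "write_tracks",
    "results_frame",
    "write_results",
]


@dataclass(frozen=True)
class PeakTrack:
    """One residue's measured shift-vs-pressure series in a protein."""

    residue_id: int
    residue_type: str
    nucleus: str
    series: PressureSeries
    variant: Optional[str] = None

    def __post_init__(self) -> None:
        if int(self.residue_id) != self.residue_id:
            raise ValueError(f"residue_id must be an integer, got {self.residue_id}")
        object.__setattr__(self, "residue_id", int(self.residue_id))


@dataclass(frozen=True)
class CorrectionResult:
    """Observed-minus-reference pressure coefficients for one track.

    ``error`` is set (and all numeric fields are None) for tracks whose
    residue/nucleus/variant cannot be resolved in the reference; such
    tracks are reported as skipped, never dropped silently.
    """

    residue_id: int
    residue_type: str
    nucleus: str
    observed: Optional[PressureCoefficients] = None
    reference: Optional[PressureCoefficients] = None
    dB1: Optional[float] = None
    dB2: Optional[float] = None
    z1: Optional[float] = None
    z2: Optional[float] = None
    flagged: bool = False
    error: Optional[str] = None

    @property
    def skipped(self) -> bool:
        return self.error is not None


def _z_score(delta: float, se_obs: Optional[float], se_ref: float) -> Optional[float]:
    if se_obs is None:  # 3-point interpolation: no observed SE available
        return None
    combined = math.sqrt(se_obs**2 + se_ref**2)
    if combined == 0.0:
        return math.inf if delta != 0.0 else 0.0
    return abs(delta) / combined


def correct_tracks(
    tracks: Iterable[PeakTrack],
    reference: Optional[ReferenceLibrary] = None,
    threshold: float = 2.0,
    z2_threshold: Optional[float] = None,
    p0: float = 0.1,
) -> List[CorrectionResult]:
    """Fit, subtract and score every track; results ordered by residue_id.

    The flag fires on ``z1 > threshold`` (first-order coefficient); the
    second-order score z2 is reported and only contributes when an
    explicit ``z2_threshold`` is given. Tracks that cannot be resolved
    in the reference, or whose series cannot be fitted, yield a result
    with ``error`` set and the pipeline continues.
    """
    if reference is None:
        reference = load_reference()
    results: List[CorrectionResult] = []
    for track in tracks:
        try:
            entry = reference.get_entry(
                track.residue_type, track.nucleus, track.variant
            )
            fit = fit_quadratic(track.series, p0=p0)
        except (ReferenceLookupError, FitError) as exc:
            results.append(
                CorrectionResult(
                    residue_id=track.residue_id,
                    residue_type=track.residue_type,
                    nucleus=track.nucleus,
                    error=str(exc),
                )
            )
            continue
        obs = fit.coefficients
        ref = entry.coefficients
        db1 = obs.B1 - ref.B1
        db2 = obs.B2 - ref.B2
        z1 = _z_score(db1, obs.B1_err, ref.B1_err)
        z2 = _z_score(db2, obs.B2_err, ref.B2_err)
        flagged = bool(z1 is not None and z1 > threshold)
        if z2_threshold is not None and z2 is not None and z2 > z2_threshold:
            flagged = True
        results.append(
            CorrectionResult(
                residue_id=track.residue_id,
                residue_type=track.residue_type,
                nucleus=track.nucleus,
                observed=obs,
                reference=ref,
                dB1=db1,
                dB2=db2,
                z1=z1,
                z2=z2,
                flagged=flagged,
            )
        )
    results.sort(key=lambda r: r.residue_id)
    return results


def residual_curve(track: PeakTrack, reference: ReferenceEntry) -> PressureSeries:
    """Pointwise observed shift minus the reference prediction.

    A purely random-coil residue leaves residuals at noise level plus a
    constant delta0 offset (sequence-context differences in the absolute
    shift survive; only the pressure response is subtracted).
    """
    if reference.nucleus.value != str(track.nucleus):
        raise ValueError(
            f"track nucleus {track.nucleus!r} does not match reference "
            f"entry {reference.key}"
        )
    predicted = predict_shift(reference.coefficients, track.series.pressures)
    return PressureSeries(
        pressures=track.series.pressures,
        shifts=track.series.shifts - predicted,
        nucleus=track.nucleus,
    )


# -- delimited-text I/O -----------------------------------------------------

_TRACK_COLUMNS = ["residue_id", "residue_type", "nucleus", "pressure_MPa", "shift_ppm"]


def read_tracks(path: Union[str, Path]) -> List[PeakTrack]:
    """Read tracks from CSV: residue_id,residue_type,nucleus,pressure_MPa,shift_ppm.

    An optional ``variant`` column selects His pH forms / Pro isomers.
    Rows are grouped by residue_id; each group must be sorted (or
    sortable) by pressure.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FitError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {_TRACK_COLUMNS}"
        )
    tracks = []
    for rid, group in df.groupby("residue_id", sort=True):
        group = group.sort_values("pressure_MPa")
        rtypes = group["residue_type"].unique()
        nuclei = group["nucleus"].unique()
        if len(rtypes) != 1 or len(nuclei) != 1:
            raise FitError(
                f"residue_id {rid}: inconsistent residue_type/nucleus rows"
            )
        variant = None
        if "variant" in group.columns:
            v = group["variant"].dropna().unique()
            if len(v) == 1:
                variant = str(v[0])
        tracks.append(
            PeakTrack(
                residue_id=int(rid),
                residue_type=str(rtypes[0]),
                nucleus=str(nuclei[0]),
                series=PressureSeries(
                    pressures=group["pressure_MPa"].to_numpy(dtype=float),
                    shifts=group["shift_ppm"].to_numpy(dtype=float),
                    nucleus=str(nuclei[0]),
                ),
                variant=variant,
            )
        )
    return tracks


def write_tracks(tracks: Sequence[PeakTrack], path: Union[str, Path]) -> None:
    rows = []
    for t in tracks:
        for p, s in zip(t.series.pressures, t.series.shifts):
            row = {
                "residue_id": t.residue_id,
                "residue_type": t.residue_type,
                "nucleus": t.nucleus,
                "pressure_MPa": p,
                "shift_ppm": s,
            }
            if t.variant is not None:
                row["variant"] = t.variant
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def results_frame(results: Sequence[CorrectionResult]) -> pd.DataFrame:
    """Tabulate correction results (one row per track, skipped included)."""
    rows = []
    for r in results:
        rows.append(
            {
                "residue_id": r.residue_id,
                "residue_type": r.residue_type,
                "nucleus": r.nucleus,
                "B1_obs": None if r.observed is None else r.observed.B1,
                "B2_obs": None if r.observed is None else r.observed.B2,
                "B1_ref": None if r.reference is None else r.reference.B1,
                "B2_ref": None if r.reference is None else r.reference.B2,
                "dB1": r.dB1,
                "dB2": r.dB2,
                "z1": r.z1,
                "z2": r.z2,
                "flagged": r.flagged,
                "error": r.error,
            }
        )
    return pd.DataFrame(rows)


def write_results(results: Sequence[CorrectionResult], path: Union[str, Path]) -> None:
    results_frame(results).to_csv(path, index=False)
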