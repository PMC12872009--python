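"""Digital-subject morphology: sampling, derived metrics, subject-table I/O.

A digital subject is described by four transverse diameters at the cervical
epicenter: the spinal cord mediolateral (SCOW) and anterior-posterior (SCOD)
diameters and the spinal canal mediolateral (SCW) and anterior-posterior
(SCD) diameters, all in mm.  Cord and canal cross-sections are modeled as
ellipses, so every other morphological measure follows in closed form:

* SCO  = pi * (SCOW/2) * (SCOD/2)      cord area, mm^2
* SC   = pi * (SCW/2)  * (SCD/2)       canal area, mm^2
* CSF area = SC - SCO                  annular cerebrospinal-fluid area
* CSF ML / CSF AP = SCW - SCOW / SCD - SCOD   diametral CSF gaps
* occlusion ratios SCO/SC, SCOW/SCW, SCOD/SCD  ("fit" of cord in canal)

Populations are drawn diameter-wise from truncated normal distributions
(moment-corrected so the truncated marginal SD equals the requested SD),
with rejection of any draw whose cord is not strictly inside the canal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SubjectMorphology",
    "PopulationSpec",
    "MorphologyError",
    "SchemaError",
    "derive_metrics",
    "sample_population",
    "read_subject_table",
    "write_subject_table",
    "subjects_to_frame",
    "MORPHOLOGY_COLUMNS",
    "RESULT_COLUMNS",
]

#: Cervical (C5) diameter statistics of the non-human-primate digital
#: population, mm (mean, SD): canal ML 11.6 +/- 0.9, cord ML 9.8 +/- 0.7,
#: canal AP 8.1 +/- 0.4, cord AP 6.3 +/- 0.4.
DEFAULT_DIAMETERS = {
    "scw": (11.6, 0.9),
    "scow": (9.8, 0.7),
    "scd": (8.1, 0.4),
    "scod": (6.3, 0.4),
}

DIAMETER_FIELDS = ("scow", "scod", "scw", "scd")

MORPHOLOGY_COLUMNS = [
    "SubjectID",
    "SCOW",
    "SCOD",
    "SCW",
    "SCD",
    "SCO",
    "SC",
    "CSF_Area",
    "CSF_ML",
    "CSF_AP",
    "Occ_Area",
    "Occ_ML",
    "Occ_AP",
]

RESULT_COLUMNS = [
    "PeakForce_N",
    "Impulse_Ns",
    "GM_Sparing_pct",
    "WM_Sparing_pct",
    "LateralExtension",
]

#: Derived columns recomputable from the four diameters, with the formula
#: applied during cross-checks on read.
_DERIVED_OF_DIAMETERS = ("SCO", "SC", "CSF_Area", "CSF_ML", "CSF_AP",
                         "Occ_Area", "Occ_ML", "Occ_AP")


class MorphologyError(ValueError):
    """A subject violates a morphological invariant (named in the message)."""


class SchemaError(ValueError):
    """A subject table does not match the expected column schema."""


@dataclass(frozen=True)
class SubjectMorphology:
    """One digital subject: four sampled diameters plus derived metrics.

    All lengths in mm, areas in mm^2, occlusion ratios dimensionless.
    """

    subject_id: str
    scow: float
    scod: float
    scw: float
    scd: float
    sco_area: float = field(default=math.nan)
    sc_area: float = field(default=math.nan)
    csf_area: float = field(default=math.nan)
    csf_ml: float = field(default=math.nan)
    csf_ap: float = field(default=math.nan)
    occ_area: float = field(default=math.nan)
    occ_ml: float = field(default=math.nan)
    occ_ap: float = field(default=math.nan)


def _validate_diameters(subject_id: str, scow: float, scod: float,
                        scw: float, scd: float) -> None:
    for name, value in (("scow", scow), ("scod", scod),
                        ("scw", scw), ("scd", scd)):
        if not (value > 0 and math.isfinite(value)):
            raise MorphologyError(
                f"subject {subject_id!r}: diameter {name}={value!r} must be "
                "a positive finite length (mm)")
    if not scow < scw:
        raise MorphologyError(
            f"subject {subject_id!r}: cord ML diameter scow={scow} must be "
            f"strictly less than canal ML diameter scw={scw}")
    if not scod < scd:
        raise MorphologyError(
            f"subject {subject_id!r}: cord AP diameter scod={scod} must be "
            f"strictly less than canal AP diameter scd={scd}")


def derive_metrics(m: SubjectMorphology) -> SubjectMorphology:
    """Fill every derived field of ``m`` from its four diameters.

    Areas use the ellipse formula pi*a*b on the semi-axes; CSF area is the
    canal/cord area difference; diametral CSF gaps are diameter differences;
    occlusion ratios are cord/canal quotients.  Idempotent, and
    scale-covariant: scaling all diameters by k scales areas by k^2 and
    leaves the occlusion ratios unchanged.

    Raises :class:`MorphologyError` (naming the offending field) for
    non-positive or inverted diameters.
    """
    _validate_diameters(m.subject_id, m.scow, m.scod, m.scw, m.scd)
    sco = math.pi * (m.scow / 2.0) * (m.scod / 2.0)
    sc = math.pi * (m.scw / 2.0) * (m.scd / 2.0)
    return replace(
        m,
        sco_area=sco,
        sc_area=sc,
        csf_area=sc - sco,
        csf_ml=m.scw - m.scow,
        csf_ap=m.scd - m.scod,
        occ_area=sco / sc,
        occ_ml=m.scow / m.scw,
        occ_ap=m.scod / m.scd,
    )


def make_subject(subject_id: str, scow: float, scod: float,
                 scw: float, scd: float) -> SubjectMorphology:
    """Build a fully derived subject from the four diameters."""
    return derive_metrics(
        SubjectMorphology(subject_id, scow, scod, scw, scd))


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling specification for a digital population.

    ``means``/``sds`` give the per-diameter normal parameters (mm); each
    diameter is truncated at ``mean +/- trunc_sd * sd``.  The pre-truncation
    SD is inflated so the *truncated* marginal SD equals the requested SD
    (so the generated population reproduces the requested spread as well as
    a bounded range).  Draws violating cord-strictly-inside-canal are
    rejected and redrawn.
    """

    n_subjects: int = 40
    means: dict[str, float] = field(
        default_factory=lambda: {k: v[0] for k, v in DEFAULT_DIAMETERS.items()})
    sds: dict[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in DEFAULT_DIAMETERS.items()})
    trunc_sd: float = 2.5
    rng_seed: int = 0
    max_attempts: int = 1000
    id_prefix: str = "S"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for k in DIAMETER_FIELDS:
            if k not in self.means or k not in self.sds:
                raise ValueError(f"means/sds must cover diameter {k!r}")
            if self.sds[k] < 0:
                raise ValueError(f"sd for {k!r} must be >= 0")
            if self.means[k] <= 0:
                raise ValueError(f"mean for {k!r} must be > 0")
        if self.trunc_sd <= 0:
            raise ValueError("trunc_sd must be > 0")


def _corrected_sigma(sd: float, trunc_sd: float) -> float:
    """Pre-truncation sigma such that truncnorm(+/- trunc_sd * sd) has SD=sd."""
    if sd == 0:
        return 0.0

    def sd_of(sigma: float) -> float:
        a = -trunc_sd * sd / sigma
        return stats.truncnorm.std(a, -a, loc=0.0, scale=sigma)

    sol = optimize.brentq(lambda s: sd_of(s) - sd, sd, 4.0 * sd)
    return float(sol)


def _draw_diameters(spec: PopulationSpec, rng: np.random.Generator,
                    size: int) -> dict[str, np.ndarray]:
    out = {}
    for k in DIAMETER_FIELDS:
        mu, sd = spec.means[k], spec.sds[k]
        if sd == 0:
            out[k] = np.full(size, mu)
            continue
        sigma = _corrected_sigma(sd, spec.trunc_sd)
        a = -spec.trunc_sd * sd / sigma
        out[k] = stats.truncnorm.rvs(a, -a, loc=mu, scale=sigma,
                                     size=size, random_state=rng)
    return out


def sample_population(spec: PopulationSpec) -> list[SubjectMorphology]:
    """Draw ``spec.n_subjects`` digital subjects.

    Deterministic for a fixed ``spec.rng_seed``.  Raises
    :class:`MorphologyError` if the cord-inside-canal constraint cannot be
    satisfied within ``spec.max_attempts`` resampling rounds (e.g. bounds
    that force the cord outside the canal); the message reports the
    offending parameters.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed),
                                                        0x5C0D]))
    accepted: list[tuple[float, float, float, float]] = []
    attempts = 0
    while len(accepted) < spec.n_subjects:
        if attempts >= spec.max_attempts:
            raise MorphologyError(
                "rejection sampling failed: could not draw a cord strictly "
                f"inside the canal after {spec.max_attempts} rounds "
                f"(means={spec.means}, sds={spec.sds}, "
                f"trunc_sd={spec.trunc_sd})")
        need = spec.n_subjects - len(accepted)
        draw = _draw_diameters(spec, rng, max(need, 8))
        ok = (draw["scow"] < draw["scw"]) & (draw["scod"] < draw["scd"])
        for i in np.flatnonzero(ok)[:need]:
            accepted.append((draw["scow"][i], draw["scod"][i],
                             draw["scw"][i], draw["scd"][i]))
        attempts += 1
    return [
        make_subject(f"{spec.id_prefix}{i + 1}", *dims)
        for i, dims in enumerate(accepted)
    ]


# ---------------------------------------------------------------------------
# Subject-table I/O (CSV, mm / mm^2 / N / N*s units; schema mirrors the
# per-subject morphology+biomechanics supplement layout)
# ---------------------------------------------------------------------------

_FIELD_OF_COLUMN = {
    "SCOW": "scow", "SCOD": "scod", "SCW": "scw", "SCD": "scd",
    "SCO": "sco_area", "SC": "sc_area", "CSF_Area": "csf_area",
    "CSF_ML": "csf_ml", "CSF_AP": "csf_ap", "Occ_Area": "occ_area",
    "Occ_ML": "occ_ml", "Occ_AP": "occ_ap",
}


def subjects_to_frame(subjects: Sequence[SubjectMorphology],
                      results: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate subjects (one row each); optionally join per-subject results.

    ``results`` is indexed by SubjectID and may carry any of the
    biomechanics columns (PeakForce_N, Impulse_Ns, GM/WM_Sparing_pct,
    LateralExtension).
    """
    rows = {
        "SubjectID": [s.subject_id for s in subjects],
        **{col: [getattr(s, f) for s in subjects]
           for col, f in _FIELD_OF_COLUMN.items()},
    }
    frame = pd.DataFrame(rows, columns=MORPHOLOGY_COLUMNS)
    if results is not None:
        frame = frame.merge(results, how="left", left_on="SubjectID",
                            right_index=True)
    return frame


def write_subject_table(subjects: Sequence[SubjectMorphology],
                        path: str | Path,
                        results: pd.DataFrame | None = None) -> pd.DataFrame:
    """Write the subject table as CSV; returns the frame written.

    Full float precision (round-trip identity with
    :func:`read_subject_table`).
    """
    frame = subjects_to_frame(subjects, results)
    # pandas' default float repr is shortest-round-trip, so write-then-read
    # reproduces every value bit-exactly
    frame.to_csv(path, index=False)
    return frame


def read_subject_table(path: str | Path, *, rel_tol: float = 5e-3,
                       ) -> tuple[list[SubjectMorphology], pd.DataFrame]:
    """Read a subject table CSV.

    Requires SubjectID and the four diameter columns; derived morphology
    columns, when present, are cross-checked against recomputation from the
    diameters at relative tolerance ``rel_tol`` (covers tables transcribed
    at printed precision) and otherwise recomputed.  Extra biomechanics
    columns are passed through in the returned frame.

    Raises :class:`SchemaError` on missing/unknown columns and
    :class:`MorphologyError` on invariant-violating rows.
    """
    frame = pd.read_csv(path)
    required = ["SubjectID", "SCOW", "SCOD", "SCW", "SCD"]
    missing = [c for c in required if c not in frame.columns]
    known = set(MORPHOLOGY_COLUMNS) | set(RESULT_COLUMNS)
    unknown = [c for c in frame.columns if c not in known]
    if missing or unknown:
        raise SchemaError(
            f"subject table {path}: missing columns {missing}, "
            f"unknown columns {unknown}")
    subjects = []
    for _, row in frame.iterrows():
        s = make_subject(str(row["SubjectID"]), float(row["SCOW"]),
                         float(row["SCOD"]), float(row["SCW"]),
                         float(row["SCD"]))
        for col in _DERIVED_OF_DIAMETERS:
            if col in frame.columns and pd.notna(row[col]):
                recomputed = getattr(s, _FIELD_OF_COLUMN[col])
                if not math.isclose(float(row[col]), recomputed,
                                    rel_tol=rel_tol, abs_tol=rel_tol):
                    raise MorphologyError(
                        f"subject {s.subject_id!r}: tabulated {col}="
                        f"{row[col]} disagrees with value recomputed from "
                        f"the diameters ({recomputed:.6g}) beyond rel_tol="
                        f"{rel_tol}")
        subjects.append(s)
    return subjects, frame
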