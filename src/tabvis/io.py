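"""Tabular formats, landmark files and the fixture generator.

Session records are long-format CSV, one row per trial, keyed by
(participant_id, test, run_index, trial_index), with test-specific payload
columns (staircase level / correctness / running estimate for faces; cell /
eccentricity / RT for search).  The first line is a schema-version comment
so files can be validated before parsing.  Participant summary tables carry
one row per participant with the two-run outcome measures and covariates;
their column names are mapped through an externalized role map so published
tables with arbitrary headers can be read without code changes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .faces import N_LANDMARKS, LandmarkFace
from .observers import Cohort, CohortConfig, generate_cohort
from .repeatability import bland_altman
from .search import SearchGrid

SESSIONS_SCHEMA = "tabvis-sessions v1"
SESSION_KEY = ["participant_id", "test", "run_index", "trial_index"]
SESSION_COLUMNS = SESSION_KEY + [
    "level_d", "correct", "threshold_estimate_d",
    "col", "row", "eccentricity_deg", "rt_s", "seed",
]

#: Canonical participant-table roles -> (required, validator description)
PARTICIPANT_ROLES = {
    "participant_id": True,
    "faces_run1": True,
    "faces_run2": True,
    "search_run1": True,
    "search_run2": True,
    "acuity_logmar": False,
    "contrast_logcs": False,
    "digit_span": False,
    "usability_faces": False,
    "usability_search": False,
}


class SchemaError(ValueError):
    """A table does not conform to the declared schema."""


# ---------------------------------------------------------------------------
# Session tables.

def cohort_to_sessions(cohort: Cohort) -> pd.DataFrame:
    """Flatten a cohort's trial-by-trial engine output to the long format."""
    rows = []
    for p in cohort.participants:
        for run_idx, sess in enumerate(p.face_runs, start=1):
            for t, ((level, correct), est) in enumerate(
                zip(sess.trials, sess.threshold_by_trial), start=1
            ):
                rows.append({
                    "participant_id": p.participant_id, "test": "faces",
                    "run_index": run_idx, "trial_index": t,
                    "level_d": level, "correct": int(correct),
                    "threshold_estimate_d": float(est), "seed": cohort.seed,
                })
        for run_idx, sess in enumerate(p.search_runs, start=1):
            for t, (loc, rt) in enumerate(sess.trials, start=1):
                col, row = cohort.grid.col_row(loc)
                rows.append({
                    "participant_id": p.participant_id, "test": "search",
                    "run_index": run_idx, "trial_index": t,
                    "col": col, "row": row,
                    "eccentricity_deg": cohort.grid.eccentricity(loc),
                    "rt_s": rt, "seed": cohort.seed,
                })
    return pd.DataFrame(rows).reindex(columns=SESSION_COLUMNS)


def _validate_sessions(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SESSION_KEY if c not in df.columns]
    if missing:
        raise SchemaError(f"session table missing key columns: {missing}")
    if len(df) == 0:
        raise SchemaError("session table is empty")
    bad_test = set(df["test"]) - {"faces", "search"}
    if bad_test:
        raise SchemaError(f"unknown test labels: {sorted(bad_test)}")
    bad_run = set(df["run_index"]) - {1, 2}
    if bad_run:
        raise SchemaError(f"run_index must be 1 or 2, found: {sorted(bad_run)}")
    dup = df.duplicated(SESSION_KEY)
    if dup.any():
        offenders = df.loc[dup, SESSION_KEY].head(5).to_dict("records")
        raise SchemaError(f"duplicate (participant, test, run, trial) keys, e.g. {offenders}")
    return df


def write_sessions(table: pd.DataFrame, path: str | Path) -> None:
    """Write a session table with its schema-version header line."""
    df = _validate_sessions(table.reindex(columns=SESSION_COLUMNS))
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {SESSIONS_SCHEMA}\n")
        df.to_csv(fh, index=False)


def read_sessions(path: str | Path) -> pd.DataFrame:
    """Read and validate a session table (schema header, key uniqueness)."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
    if first != f"# {SESSIONS_SCHEMA}":
        raise SchemaError(
            f"{path}: expected schema header '# {SESSIONS_SCHEMA}', found {first!r}"
        )
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: no rows in session table") from None
    return _validate_sessions(df)


# ---------------------------------------------------------------------------
# Participant tables.

def cohort_to_participants(
    cohort: Cohort,
    n_face_trials: int | None = None,
    search_subset: Sequence[int] | None = None,
) -> pd.DataFrame:
    """One row per participant: two-run outcomes (faces threshold at the
    analysis trial count; search median RT over the analysis subset) plus
    covariates.  Faces outcomes are NaN for participants whose faces data
    are not reported."""
    f1, f2 = cohort.faces_pairs(n_face_trials)
    s1, s2 = cohort.search_pairs(search_subset)
    rows = []
    fi = 0
    for i, p in enumerate(cohort.participants):
        faces = (f1[fi], f2[fi]) if p.faces_reported else (np.nan, np.nan)
        if p.faces_reported:
            fi += 1
        rows.append({
            "participant_id": p.participant_id,
            "faces_run1": faces[0], "faces_run2": faces[1],
            "search_run1": s1[i], "search_run2": s2[i],
            **p.covariates,
        })
    df = pd.DataFrame(rows)
    return df.rename(columns={
        "acuity_logmar": "acuity_logmar", "contrast_logcs": "contrast_logcs",
    })


def read_participants(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a participant summary table through a role -> column map.

    ``column_map`` maps canonical roles (faces_run1, search_run2,
    usability_faces, ...) to the file's actual headers; by default roles map
    to identically-named columns.  Required roles must resolve; values are
    validated (ratings within 0-10, outcome measures positive).
    """
    path = Path(path)
    raw = pd.read_csv(path, comment="#")
    column_map = dict(column_map or {})
    out = {}
    for role, required in PARTICIPANT_ROLES.items():
        col = column_map.get(role, role)
        if col not in raw.columns:
            if required:
                raise SchemaError(
                    f"{path}: no column for required role '{role}' (looked for {col!r})"
                )
            continue
        out[role] = raw[col]
    df = pd.DataFrame(out)
    for role in ("faces_run1", "faces_run2", "search_run1", "search_run2"):
        vals = df[role].dropna()
        if (vals <= 0).any():
            raise SchemaError(f"{path}: role '{role}' must be strictly positive")
    for role in ("usability_faces", "usability_search"):
        if role in df:
            vals = df[role].dropna()
            if ((vals < 0) | (vals > 10)).any():
                raise SchemaError(f"{path}: role '{role}' ratings must lie in [0, 10]")
    return df


def write_participants(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Landmark files.

def read_landmarks(path: str | Path, face_id: str | None = None) -> LandmarkFace:
    """Read a face landmark file: 127 lines of 'x y'."""
    path = Path(path)
    pts = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise SchemaError(f"{path}:{lineno}: expected 'x y', got {line!r}")
        pts.append((float(parts[0]), float(parts[1])))
    if len(pts) != N_LANDMARKS:
        raise SchemaError(f"{path}: expected {N_LANDMARKS} landmark points, found {len(pts)}")
    return LandmarkFace(points=np.array(pts), face_id=face_id or path.stem)


def write_landmarks(face: LandmarkFace, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{x:.6f} {y:.6f}\n" for x, y in face.points)
    )


# ---------------------------------------------------------------------------
# Fixtures.

def make_fixtures(out_dir: str | Path, seed: int = 0) -> Path:
    """Write a deterministic worked-example directory: a full synthetic
    cohort (sessions + participants CSV), two toy landmark faces, and an
    expected-output JSON computed from a fresh analysis of those files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config=CohortConfig(), seed=seed)
    grid = cohort.grid
    sub22 = grid.refined_subset()
    write_sessions(cohort_to_sessions(cohort), out / "sessions.csv")
    write_participants(
        cohort_to_participants(cohort, n_face_trials=20, search_subset=sub22),
        out / "participants.csv",
    )
    rng = np.random.default_rng(seed)
    base = LandmarkFace(rng.uniform(0, 100, size=(N_LANDMARKS, 2)), "toy_standard")
    other = LandmarkFace(base.points + rng.normal(0, 0.5, size=(N_LANDMARKS, 2)),
                         "toy_target")
    write_landmarks(base, out / "face_standard.txt")
    write_landmarks(other, out / "face_target.txt")

    f1, f2 = cohort.faces_pairs(20)
    s1, s2 = cohort.search_pairs(sub22)
    expected = {
        "seed": seed,
        "n_participants": len(cohort.participants),
        "n_faces_reported": int(sum(p.faces_reported for p in cohort.participants)),
        "faces_cor95_d": bland_altman(f1, f2, ci=False).cor95,
        "search_cor95_s": bland_altman(s1, s2, ci=False).cor95,
    }
    (out / "expected.json").write_text(json.dumps(expected, indent=2, sort_keys=True))
    return out
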