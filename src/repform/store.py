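"""The labeled-repetition session database and model persistence.

A :class:`SessionDatabase` keys repetitions by
``(session_id, exercise, rep_number)``, keeps a per-exercise label
vocabulary (always containing the default "Acceptable" class), and
tracks which repetitions still await manual review.  On disk the
database is one JSON document referencing per-session 18-channel signal
CSVs, with each repetition stored as boundary indices into its session's
signals rather than duplicated sample data.

Trained classifiers are serialized as joblib archives with an embedded
format-version field.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import pandas as pd

from .preprocess import SignalSet
from .segment import DEFAULT_LABEL, Repetition

__all__ = [
    "SessionDatabase",
    "ModelFileError",
    "save_model",
    "load_model",
    "save_database",
    "load_database",
]

MODEL_FORMAT_VERSION = 1
DATABASE_FORMAT_VERSION = 1


class ModelFileError(ValueError):
    """A model file is corrupt, truncated, or of an unsupported version."""


class SessionDatabase:
    """In-memory store of segmented, labeled exercise repetitions."""

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str, int], Repetition] = {}
        self._sessions: dict[str, SignalSet] = {}
        self.label_vocabulary: dict[str, list[str]] = {}
        self.pending_review: set[tuple[str, str, int]] = set()

    # -- vocabulary -----------------------------------------------------

    def add_exercise(self, exercise: str) -> None:
        """Register an exercise; its vocabulary starts with the default class."""
        self.label_vocabulary.setdefault(exercise, [DEFAULT_LABEL])

    def add_label(self, exercise: str, label: str) -> None:
        """Register a technique label for an exercise (unlimited labels allowed)."""
        self.add_exercise(exercise)
        if label not in self.label_vocabulary[exercise]:
            self.label_vocabulary[exercise].append(label)

    # -- entries --------------------------------------------------------

    def add_repetition(self, rep: Repetition) -> None:
        if rep.key in self._entries:
            raise KeyError(f"repetition {rep.key} already stored")
        self.add_exercise(rep.exercise)
        if rep.label not in self.label_vocabulary[rep.exercise]:
            self.add_label(rep.exercise, rep.label)
        self._entries[rep.key] = rep

    def add_session(
        self,
        signals: SignalSet,
        reps: list[Repetition],
        labeled: bool = False,
    ) -> None:
        """Store a session's signal set and its segmented repetitions."""
        if reps:
            sid = reps[0].session_id
            self._sessions[sid] = signals
        for rep in reps:
            rep.labeled = rep.labeled or labeled
            self.add_repetition(rep)

    def get(self, key: tuple[str, str, int]) -> Repetition:
        if key not in self._entries:
            raise KeyError(f"no repetition {key} in database")
        return self._entries[key]

    def keys(self) -> list[tuple[str, str, int]]:
        return list(self._entries.keys())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key) -> bool:
        return key in self._entries

    def session_signals(self, session_id: str) -> SignalSet:
        return self._sessions[session_id]

    # -- label management ------------------------------------------------

    def relabel(self, key: tuple[str, str, int], label: str) -> None:
        """Set a repetition's label; the label must be in the exercise's
        vocabulary."""
        rep = self.get(key)
        vocab = self.label_vocabulary.get(rep.exercise, [DEFAULT_LABEL])
        if label not in vocab:
            raise ValueError(
                f"label {label!r} is not registered for exercise {rep.exercise!r}; "
                f"known labels: {vocab}"
            )
        rep.label = label
        rep.labeled = True
        self.pending_review.discard(key)

    def remove_rep(self, key: tuple[str, str, int]) -> None:
        if key not in self._entries:
            raise KeyError(f"no repetition {key} to remove")
        del self._entries[key]
        self.pending_review.discard(key)

    def mark_for_review(self, key: tuple[str, str, int]) -> None:
        self.get(key)  # must exist
        self.pending_review.add(key)

    def labels_for(self, exercise: str) -> dict[tuple[str, str, int], str]:
        return {k: r.label for k, r in self._entries.items() if k[1] == exercise}


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def save_model(results, path: str | Path) -> Path:
    """Serialize a trained :class:`~repform.classify.TechniqueForestResults`.

    Refuses anything that is not a fitted results object (an unfit model
    has no ensemble to export).
    """
    from .classify import TechniqueForestResults

    if not isinstance(results, TechniqueForestResults):
        raise TypeError(
            "save_model expects a fitted TechniqueForestResults; "
            f"got {type(results).__name__} (call .fit() first)"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "results": results}, path)
    return path


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`.

    A truncated or foreign file raises :class:`ModelFileError` rather
    than failing silently or returning partial state.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        payload = joblib.load(path)
    except Exception as exc:  # noqa: BLE001 - any unpickling failure is corrupt
        raise ModelFileError(f"{path}: corrupt or unreadable model file ({exc})") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFileError(f"{path}: not a repform model archive")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFileError(
            f"{path}: unsupported model format version {payload['format_version']} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return payload["results"]


# ---------------------------------------------------------------------------
# database persistence
# ---------------------------------------------------------------------------


def save_database(db: SessionDatabase, directory: str | Path) -> Path:
    """Write a database as ``db.json`` plus one signal CSV per session.

    Repetition epochs are stored as slice indices into the session
    signals, not duplicated.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sessions = {}
    for sid, signals in db._sessions.items():
        csv_name = f"{sid}.signals.csv"
        signals.to_dataframe().to_csv(directory / csv_name, index=False, float_format="%.12g")
        sessions[sid] = {
            "signals_csv": csv_name,
            "fs": signals.fs,
            "exercise": signals.exercise,
        }
    doc = {
        "format_version": DATABASE_FORMAT_VERSION,
        "label_vocabulary": db.label_vocabulary,
        "pending_review": sorted(list(k) for k in db.pending_review),
        "sessions": sessions,
        "entries": [
            {
                "session_id": r.session_id,
                "exercise": r.exercise,
                "rep_number": r.rep_number,
                "start_index": r.start_index,
                "peak_index": r.peak_index,
                "end_index": r.end_index,
                "label": r.label,
                "labeled": r.labeled,
            }
            for r in db._entries.values()
        ],
    }
    (directory / "db.json").write_text(json.dumps(doc, indent=1))
    return directory / "db.json"


def load_database(directory: str | Path) -> SessionDatabase:
    """Rebuild a database written by :func:`save_database`."""
    directory = Path(directory)
    doc = json.loads((directory / "db.json").read_text())
    if doc.get("format_version") != DATABASE_FORMAT_VERSION:
        raise ValueError(f"unsupported database format version {doc.get('format_version')}")
    db = SessionDatabase()
    signal_sets = {}
    for sid, info in doc["sessions"].items():
        df = pd.read_csv(directory / info["signals_csv"])
        signal_sets[sid] = SignalSet.from_dataframe(
            df, fs=info["fs"], session_id=sid, exercise=info["exercise"]
        )
        db._sessions[sid] = signal_sets[sid]
    for exercise, labels in doc["label_vocabulary"].items():
        for label in labels:
            db.add_label(exercise, label)
    for entry in doc["entries"]:
        sid = entry["session_id"]
        rep = Repetition(
            session_id=sid,
            exercise=entry["exercise"],
            rep_number=entry["rep_number"],
            start_index=entry["start_index"],
            peak_index=entry["peak_index"],
            end_index=entry["end_index"],
            signals=signal_sets[sid].slice(entry["start_index"], entry["end_index"]),
            label=entry["label"],
            labeled=entry["labeled"],
        )
        db.add_repetition(rep)
    db.pending_review = {tuple(k) for k in doc.get("pending_review", [])}
    return db
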