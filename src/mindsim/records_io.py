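"""Serialization: play records as JSON Lines, summaries as CSV, manifests.

Records are written one JSON object per line with an explicit schema tag so
that future format changes fail loudly rather than silently. States are
stored as their nine-integer tuples; actions and feedback by name.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

from .simulation import PlayRecord, Step
from .water_task import Action, AgeClass, Feedback, GameState, Valence

__all__ = ["SCHEMA", "write_records", "read_records", "write_manifest"]

SCHEMA = "mindsim-playrecord-v1"


def _feedback_to_obj(f: Feedback):
    if f.valence == Valence.NONE:
        return None
    return {"valence": f.valence.value, "tag": f.tag, "age": f.age.name}


def _feedback_from_obj(obj) -> Feedback:
    if obj is None:
        return Feedback(valence=Valence.NONE)
    return Feedback(
        valence=Valence(obj["valence"]), tag=obj["tag"], age=AgeClass[obj["age"]]
    )


def record_to_dict(r: PlayRecord) -> dict:
    return {
        "schema": SCHEMA,
        "player_id": r.player_id,
        "mindset": r.mindset,
        "beta": r.beta,
        "run_index": r.run_index,
        "seed": r.seed,
        "end_reason": r.end_reason,
        "steps": [
            {
                "s": list(s.state_before.as_tuple()),
                "a": s.action.name,
                "f": _feedback_to_obj(s.feedback),
                "s2": list(s.state_after.as_tuple()),
            }
            for s in r.steps
        ],
    }


def record_from_dict(obj: dict) -> PlayRecord:
    if obj.get("schema") != SCHEMA:
        raise ValueError(
            f"unsupported record schema {obj.get('schema')!r} (expected {SCHEMA})"
        )
    steps = [
        Step(
            state_before=GameState.from_tuple(tuple(s["s"])),
            action=Action[s["a"]],
            feedback=_feedback_from_obj(s["f"]),
            state_after=GameState.from_tuple(tuple(s["s2"])),
        )
        for s in obj["steps"]
    ]
    return PlayRecord(
        player_id=obj["player_id"],
        mindset=obj["mindset"],
        beta=float(obj["beta"]),
        run_index=int(obj["run_index"]),
        seed=int(obj["seed"]),
        steps=steps,
        end_reason=obj["end_reason"],
    )


def write_records(path, records: Iterable[PlayRecord]) -> None:
    """Write records as JSON Lines (sorted keys: byte-stable for fixed input)."""
    path = Path(path)
    with path.open("w") as fh:
        for r in records:
            fh.write(json.dumps(record_to_dict(r), sort_keys=True) + "\n")


def read_records(path) -> list[PlayRecord]:
    path = Path(path)
    out: list[PlayRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"{path}:{lineno}: malformed record line: {e}") from e
            out.append(record_from_dict(obj))
    return out


def config_checksum(config_dict: dict) -> str:
    """SHA-256 of the canonical-JSON config; embedded in every artifact."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path, config_dict: dict, extra: dict | None = None) -> None:
    payload = {
        "schema": "mindsim-manifest-v1",
        "config": config_dict,
        "config_checksum": config_checksum(config_dict),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
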