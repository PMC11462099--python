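"""File formats: notes JSONL/CSV in, evidence/labels/metrics out."""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .evaluate import GoldLabel
from .mentions import SeverityMention
from .notes import NoteDocument
from .resolve import PatientSeverity
from .scores import ScoreMention
from .synth import LabeledNote


class NotesFormatError(ValueError):
    """An input file does not follow the documented note schema."""


def _parse_date(value) -> Optional[datetime.date]:
    if value in (None, ""):
        return None
    if isinstance(value, datetime.date):
        return value
    try:
        return datetime.date.fromisoformat(str(value))
    except ValueError as exc:
        raise NotesFormatError(f"bad note_date {value!r}: {exc}") from exc


def _note_from_record(rec: dict, where: str) -> NoteDocument:
    try:
        return NoteDocument(
            patient_id=str(rec["patient_id"]),
            note_id=str(rec["note_id"]),
            text=str(rec.get("text") or ""),
            note_date=_parse_date(rec.get("note_date")),
        )
    except (KeyError, ValueError) as exc:
        raise NotesFormatError(f"{where}: {exc}") from exc


def read_notes(path) -> List[NoteDocument]:
    """Read notes from JSONL (``.jsonl``/``.json``) or CSV.

    Each record needs ``patient_id``, ``note_id`` and ``text`` fields;
    ``note_date`` (ISO format) is optional.  Errors name the offending
    line or row.
    """
    path = Path(path)
    notes: List[NoteDocument] = []
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in ("patient_id", "note_id", "text"):
            if col not in frame.columns:
                raise NotesFormatError(f"{path}: missing column {col!r}")
        for i, rec in enumerate(frame.to_dict("records")):
            notes.append(_note_from_record(rec, f"{path} row {i + 1}"))
        return notes
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise NotesFormatError(
                    f"{path} line {lineno}: invalid JSON: {exc}"
                ) from exc
            if not isinstance(rec, dict):
                raise NotesFormatError(f"{path} line {lineno}: not an object")
            notes.append(_note_from_record(rec, f"{path} line {lineno}"))
    return notes


def write_notes(notes: Iterable[NoteDocument], path) -> None:
    """Write notes as JSONL, one object per note."""
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "patient_id": n.patient_id,
                        "note_id": n.note_id,
                        "note_date": n.note_date.isoformat() if n.note_date else None,
                        "text": n.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def write_evidence(
    mentions: Sequence[SeverityMention],
    scores: Sequence[ScoreMention],
    path,
) -> None:
    """Evidence JSONL: one record per finding, both branches."""
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                json.dumps(
                    {
                        "branch": "text",
                        "note_id": m.note_id,
                        "trigger": m.trigger,
                        "severity_term": m.severity_term,
                        "severity": m.severity,
                        "trigger_span": [m.trigger_start, m.trigger_end],
                        "severity_span": [m.severity_start, m.severity_end],
                    }
                )
                + "\n"
            )
        for s in scores:
            fh.write(
                json.dumps(
                    {
                        "branch": "score",
                        "note_id": s.note_id,
                        "test": s.test_name,
                        "raw": s.raw,
                        "value": s.value,
                        "variant": s.format_variant,
                        "valid": s.valid,
                        "severity": s.severity,
                        "span": [s.start, s.end],
                    }
                )
                + "\n"
            )


def write_patients_csv(results: Sequence[PatientSeverity], path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "severity": r.severity,
                "source": r.source,
                "n_text_evidence": r.n_text_evidence,
                "n_score_evidence": r.n_score_evidence,
            }
            for r in results
        ],
        columns=[
            "patient_id",
            "severity",
            "source",
            "n_text_evidence",
            "n_score_evidence",
        ],
    ).to_csv(path, index=False)


def read_patients_csv(path) -> List[PatientSeverity]:
    """Re-read a patient CSV as labels (evidence trail not round-tripped)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for rec in frame.to_dict("records"):
        out.append(
            PatientSeverity(
                patient_id=rec["patient_id"],
                severity=rec["severity"],
                source=rec["source"],
            )
        )
    return out


def write_gold_csv(gold: Sequence[GoldLabel], path) -> None:
    pd.DataFrame(
        [
            {
                "record_id": g.record_id,
                "has_severity_info": str(g.has_severity_info).lower(),
                "severity": g.severity or "",
            }
            for g in gold
        ],
        columns=["record_id", "has_severity_info", "severity"],
    ).to_csv(path, index=False)


def read_gold_csv(path) -> List[GoldLabel]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if len(frame) == 0:
        raise NotesFormatError(f"{path}: gold file is empty")
    for col in ("record_id", "has_severity_info"):
        if col not in frame.columns:
            raise NotesFormatError(f"{path}: missing column {col!r}")
    out = []
    for i, rec in enumerate(frame.to_dict("records")):
        flag = str(rec["has_severity_info"]).strip().lower()
        if flag not in ("true", "false", "1", "0"):
            raise NotesFormatError(
                f"{path} row {i + 1}: has_severity_info must be true/false"
            )
        out.append(
            GoldLabel(
                record_id=rec["record_id"],
                has_severity_info=flag in ("true", "1"),
                severity=rec.get("severity") or None,
            )
        )
    return out


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_audit_log(entries: Sequence[dict], path) -> None:
    """Plain-text audit log, one reason-coded line per item."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            reason = e.get("reason", "unknown")
            rest = " ".join(
                f"{k}={e[k]!r}" for k in sorted(e) if k != "reason"
            )
            fh.write(f"{reason}\t{rest}\n")


def write_corpus(notes: Sequence[LabeledNote], outdir) -> dict:
    """Write a synthetic corpus: notes JSONL + gold CSV + annotations JSONL."""
    from .synth import corpus_gold

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    notes_path = outdir / "notes.jsonl"
    gold_path = outdir / "gold.csv"
    ann_path = outdir / "annotations.jsonl"
    write_notes([ln.note for ln in notes], notes_path)
    write_gold_csv(corpus_gold(notes), gold_path)
    with open(ann_path, "w", encoding="utf-8") as fh:
        for ln in notes:
            for a in ln.annotations:
                rec = {"note_id": ln.note.note_id, **asdict(a)}
                fh.write(json.dumps(rec) + "\n")
    return {"notes": str(notes_path), "gold": str(gold_path), "annotations": str(ann_path)}
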