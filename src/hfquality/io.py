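"""Readers and writers for the on-disk corpus, results, and gold formats.

Corpus layout on disk::

    corpus_dir/
      metadata.tsv        note_id  patient_id  note_datetime  title  [text_file | text]
      notes/<note_id>.txt one UTF-8 file per note (when text is not inline)

Results and gold annotations are JSON-lines, one record per patient.  Gold
can also be imported from the widely used BRAT-style standoff dialect
(``T1<TAB>TYPE START END<TAB>TEXT`` lines in a ``.ann`` file next to the
note).
"""

from __future__ import annotations

import csv
import json
import logging
import re
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional

from .types import (
    ClinicalNote,
    Concept,
    ConceptMention,
    Corpus,
    DocType,
    GoldAnnotation,
    PatientDeterminations,
)

log = logging.getLogger(__name__)

METADATA_COLUMNS = ["note_id", "patient_id", "note_datetime", "title"]


class CorpusFormatError(ValueError):
    """A malformed corpus, gold, or results file."""


def _parse_datetime(raw: str, where: str) -> Optional[datetime]:
    raw = (raw or "").strip()
    if not raw:
        log.warning("%s: missing datetime; note will sort before dated notes", where)
        return None
    try:
        return datetime.fromisoformat(raw)
    except ValueError:
        log.warning("%s: unparseable datetime %r; treated as undated", where, raw)
        return None


def read_corpus(path: str | Path, map_title=None) -> Corpus:
    """Read a corpus directory into memory.

    ``map_title`` maps a document title to a :class:`DocType`; by default the
    shipped title-mapping table is used.  A ``doc_type`` metadata column, if
    present, wins over title mapping.
    """
    if map_title is None:
        from .preprocess import map_document_type as map_title

    path = Path(path)
    meta = path / "metadata.tsv"
    if not meta.is_file():
        raise CorpusFormatError(f"no metadata.tsv in {path}")

    corpus = Corpus()
    with open(meta, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return corpus  # empty file -> empty corpus
        missing = [c for c in METADATA_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CorpusFormatError(f"{meta}: missing columns {missing}")
        for i, row in enumerate(reader, start=2):
            where = f"{meta}:{i}"
            note_id = (row.get("note_id") or "").strip()
            patient_id = (row.get("patient_id") or "").strip()
            if not note_id:
                raise CorpusFormatError(f"{where}: record missing note_id")
            if not patient_id:
                raise CorpusFormatError(
                    f"{where}: record {note_id!r} missing patient_id"
                )
            if row.get("text") is not None and row["text"] != "":
                text = row["text"].replace("\\n", "\n")
            else:
                rel = (row.get("text_file") or "").strip() or f"notes/{note_id}.txt"
                text_path = path / rel
                if not text_path.is_file():
                    raise CorpusFormatError(f"{where}: note text file {rel} not found")
                text = text_path.read_text(encoding="utf-8")
            note = ClinicalNote(
                note_id=note_id,
                patient_id=patient_id,
                note_datetime=_parse_datetime(row.get("note_datetime", ""), where),
                title=row.get("title", ""),
                text=text,
            )
            if (row.get("doc_type") or "").strip():
                note.doc_type = DocType(row["doc_type"].strip())
            else:
                note.doc_type = map_title(note.title)
            try:
                corpus.add(note)
            except ValueError as exc:
                raise CorpusFormatError(f"{where}: {exc}") from exc
    return corpus


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus directory (metadata.tsv + notes/*.txt)."""
    path = Path(path)
    notes_dir = path / "notes"
    notes_dir.mkdir(parents=True, exist_ok=True)
    with open(path / "metadata.tsv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(METADATA_COLUMNS + ["doc_type", "text_file"])
        for note in corpus:
            rel = f"notes/{note.note_id}.txt"
            (path / rel).write_text(note.text, encoding="utf-8")
            writer.writerow(
                [
                    note.note_id,
                    note.patient_id,
                    note.note_datetime.isoformat() if note.note_datetime else "",
                    note.title,
                    note.doc_type.value,
                    rel,
                ]
            )


# --- results (patient determinations) -------------------------------------

RESULTS_SCHEMA = "hfquality/determinations/v1"


def write_results(
    determinations: Iterable[PatientDeterminations], path: str | Path
) -> None:
    """Write determinations as JSON-lines with a leading schema record."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"schema": RESULTS_SCHEMA}) + "\n")
        for det in determinations:
            fh.write(json.dumps(det.to_dict()) + "\n")


def read_results(path: str | Path) -> list[PatientDeterminations]:
    out: list[PatientDeterminations] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{i}: bad JSON: {exc}") from exc
            if "schema" in rec:
                if rec["schema"] != RESULTS_SCHEMA:
                    raise CorpusFormatError(
                        f"{path}:{i}: unexpected schema {rec['schema']!r}"
                    )
                continue
            out.append(PatientDeterminations.from_dict(rec))
    return out


# --- gold annotations ------------------------------------------------------

GOLD_SCHEMA = "hfquality/gold/v1"


def write_gold(gold: Iterable[GoldAnnotation], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"schema": GOLD_SCHEMA}) + "\n")
        for ann in gold:
            fh.write(json.dumps(ann.to_dict()) + "\n")


def read_gold(path: str | Path, corpus: Optional[Corpus] = None) -> list[GoldAnnotation]:
    """Read native gold JSON-lines.  If ``corpus`` is given, every mention
    span is validated against the note it points into."""
    out: list[GoldAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            if "schema" in rec:
                continue
            ann = GoldAnnotation.from_dict(rec)
            if corpus is not None:
                _validate_spans(ann, corpus, f"{path}:{i}")
            out.append(ann)
    return out


def _validate_spans(ann: GoldAnnotation, corpus: Corpus, where: str) -> None:
    for m in ann.mentions:
        try:
            note = corpus.get_note(m.note_id)
        except KeyError:
            raise CorpusFormatError(
                f"{where}: mention references unknown note {m.note_id!r}"
            ) from None
        if not (0 <= m.start < m.end <= len(note.text)):
            raise CorpusFormatError(
                f"{where}: mention span [{m.start}, {m.end}) outside note "
                f"{m.note_id!r} of length {len(note.text)}"
            )


# BRAT-style standoff: "T1<TAB>TYPE START END<TAB>TEXT"
_BRAT_LINE = re.compile(
    r"^(?P<id>T\d+)\t(?P<type>\S+)\s+(?P<start>\d+)\s+(?P<end>\d+)\t(?P<text>.*)$"
)

_BRAT_CONCEPTS = {
    "EF": Concept.EF_MENTION,
    "EF_MENTION": Concept.EF_MENTION,
    "LVEF": Concept.EF_MENTION,
    "ACEI_ARB": Concept.ACEI_ARB,
    "MEDICATION": Concept.ACEI_ARB,
    "RNM": Concept.RNM,
}


def read_brat(ann_path: str | Path, note: ClinicalNote) -> list[ConceptMention]:
    """Import text-bound annotations from a BRAT-style ``.ann`` file.

    Only the concept, span, and surface text are recoverable from this
    dialect; normalized values must be re-derived (e.g. with the extractors).
    """
    mentions: list[ConceptMention] = []
    for i, line in enumerate(Path(ann_path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or not line.startswith("T"):
            continue
        m = _BRAT_LINE.match(line)
        if m is None:
            raise CorpusFormatError(f"{ann_path}:{i}: unparseable standoff line")
        start, end = int(m.group("start")), int(m.group("end"))
        if not (0 <= start < end <= len(note.text)):
            raise CorpusFormatError(
                f"{ann_path}:{i}: annotation {m.group('id')} span [{start}, {end}) "
                f"outside note of length {len(note.text)}"
            )
        covered = note.text[start:end]
        if m.group("text") and covered != m.group("text"):
            raise CorpusFormatError(
                f"{ann_path}:{i}: annotation {m.group('id')} text mismatch: "
                f"file says {m.group('text')!r}, note has {covered!r}"
            )
        concept = _BRAT_CONCEPTS.get(m.group("type").upper())
        if concept is None:
            log.warning("%s:%d: skipping unknown annotation type %r", ann_path, i, m.group("type"))
            continue
        mentions.append(
            ConceptMention(concept=concept, note_id=note.note_id, start=start, end=end)
        )
    return mentions


__all__ = [
    "CorpusFormatError",
    "read_brat",
    "read_corpus",
    "read_gold",
    "read_results",
    "write_corpus",
    "write_gold",
    "write_results",
]
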