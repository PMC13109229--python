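"""Reading and writing label sequences and group manifests.

Label files are plain text with one label per line — either integers
(0..K-1) or single letters (A..Z, mapped alphabetically to 0..25) — or a
single-column CSV with header ``label``.  A manifest is a JSON file listing
the sequence files of one cohort:

    {"group": "CN", "K": 4, "kind": "continuous",
     "files": ["sub-01.txt", ...], "truncate": "min"}

Paths are resolved relative to the manifest location.  ``truncate`` may be
``"min"`` (cut every sequence to the cohort minimum length, the default),
an integer length, or ``null`` (no truncation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParseError
from .sequence import CONTINUOUS, JUMP, MicrostateSequence, labels_to_letters

__all__ = ["read_labels", "read_sequence", "write_sequence", "Manifest", "load_manifest"]


def read_labels(path: str | Path) -> np.ndarray:
    """Parse a label file into an integer array (no alphabet validation)."""
    path = Path(path)
    labels: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            tok = raw.strip()
            if not tok:
                continue
            if lineno == 1 and tok.lower() == "label":
                continue  # CSV header
            tok = tok.rstrip(",")
            if tok.lstrip("-").isdigit():
                value = int(tok)
                if value < 0:
                    raise ParseError(f"negative label {value}", path, lineno)
            elif len(tok) == 1 and tok.isalpha():
                value = ord(tok.upper()) - ord("A")
            else:
                raise ParseError(f"malformed label {tok!r}", path, lineno)
            labels.append(value)
    if not labels:
        raise ParseError("file contains no labels", path)
    return np.asarray(labels, dtype=np.int64)


def read_sequence(
    path: str | Path,
    n_states: int | None = None,
    kind: str = CONTINUOUS,
    sampling_rate_hz: float | None = None,
) -> MicrostateSequence:
    """Read a label file as a :class:`MicrostateSequence`.

    When ``n_states`` is given, labels outside [0, K-1] are rejected; when
    omitted, K is inferred as max label + 1.
    """
    labels = read_labels(path)
    K = int(labels.max()) + 1 if n_states is None else n_states
    if labels.max() >= K:
        raise ParseError(f"label {labels.max()} outside alphabet of size {K}", path)
    return MicrostateSequence(
        labels, K, kind=kind, sampling_rate_hz=sampling_rate_hz, subject_id=Path(path).stem
    )


def write_sequence(seq: MicrostateSequence, path: str | Path, letters: bool = False) -> None:
    """Write one label per line; ``letters=True`` writes A/B/C/... instead."""
    path = Path(path)
    if letters:
        lines = list(labels_to_letters(seq.labels))
    else:
        lines = [str(int(x)) for x in seq.labels]
    path.write_text("\n".join(lines) + "\n")


@dataclass
class Manifest:
    group: str
    n_states: int
    kind: str
    files: list[Path]
    truncate: str | int | None = "min"

    def load(self) -> list[MicrostateSequence]:
        """Read all sequences, applying the manifest truncation policy."""
        seqs = [read_sequence(f, n_states=self.n_states, kind=self.kind) for f in self.files]
        if self.truncate is None:
            return seqs
        limit = min(len(s) for s in seqs) if self.truncate == "min" else int(self.truncate)
        out = []
        for s in seqs:
            if len(s) < limit:
                raise ParseError(
                    f"sequence {s.subject_id} shorter ({len(s)}) than truncation length {limit}"
                )
            out.append(
                MicrostateSequence(
                    s.labels[:limit], s.n_states, kind=s.kind, subject_id=s.subject_id
                )
            )
        return out


def load_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}", path) from exc
    for key in ("group", "K", "kind", "files"):
        if key not in data:
            raise ParseError(f"manifest missing required key {key!r}", path)
    if data["kind"] not in (CONTINUOUS, JUMP):
        raise ParseError(f"manifest kind must be 'continuous' or 'jump'", path)
    files = [path.parent / f for f in data["files"]]
    missing = [str(f) for f in files if not f.exists()]
    if missing:
        raise ParseError(f"manifest refers to missing files: {missing}", path)
    if not files:
        raise ParseError("manifest lists no files", path)
    return Manifest(
        group=str(data["group"]),
        n_states=int(data["K"]),
        kind=data["kind"],
        files=files,
        truncate=data.get("truncate", "min"),
    )
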