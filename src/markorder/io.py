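"""Reading and writing sequence tables, results and reports.

Sequences travel as TSV with header columns ``subject_id``, ``trial_id``,
``sequence`` ('#'-prefixed comment lines ignored, UTF-8); results as JSON;
human-readable reports as Markdown.  A remap option converts foreign
symbol pairs (e.g. '0'/'1') to the alphabet on ingest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .models import Alphabet, DEFAULT_ALPHABET
from .simulate import BenchmarkDataset
from .stats import SymbolSequence

REQUIRED_COLUMNS = ("subject_id", "trial_id", "sequence")


@dataclass(frozen=True)
class SequenceTable:
    """Validated collection of trials, grouped on demand by subject."""

    sequences: tuple[SymbolSequence, ...]
    alphabet: Alphabet = field(default=DEFAULT_ALPHABET)

    def __post_init__(self) -> None:
        seen = set()
        for s in self.sequences:
            key = (s.subject_id, s.trial_id)
            if key in seen:
                raise ValueError(f"duplicate trial key {key}")
            seen.add(key)
        object.__setattr__(self, "sequences", tuple(self.sequences))

    def __len__(self) -> int:
        return len(self.sequences)

    def by_subject(self) -> dict[str, list[SymbolSequence]]:
        out: dict[str, list[SymbolSequence]] = {}
        for s in self.sequences:
            out.setdefault(s.subject_id, []).append(s)
        return out


def read_sequences(
    path: str | Path,
    alphabet: Alphabet = DEFAULT_ALPHABET,
    remap: dict[str, str] | None = None,
) -> SequenceTable:
    """Load and validate a TSV sequence table.

    ``remap`` translates characters before validation, e.g.
    ``{"0": "L", "1": "R"}`` to ingest binary-coded files.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no sequence rows")
    sequences = []
    for row_num, row in enumerate(df.itertuples(index=False), start=1):
        text = row.sequence
        if remap:
            text = "".join(remap.get(ch, ch) for ch in text)
        try:
            sequences.append(
                SymbolSequence(row.subject_id, row.trial_id, text, alphabet)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: data row {row_num}: {exc}") from None
    try:
        return SequenceTable(tuple(sequences), alphabet)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_sequences(path: str | Path, sequences) -> None:
    """Write trials to the TSV sequence format."""
    df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in sequences],
            "trial_id": [s.trial_id for s in sequences],
            "sequence": [s.symbols for s in sequences],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_plain_sequences(
    path: str | Path,
    subject_id: str = "subject",
    alphabet: Alphabet = DEFAULT_ALPHABET,
    remap: dict[str, str] | None = None,
) -> SequenceTable:
    """Import shim for one-sequence-per-line text files."""
    sequences = []
    with open(path, encoding="utf-8") as fh:
        for k, line in enumerate(fh):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            if remap:
                text = "".join(remap.get(ch, ch) for ch in text)
            sequences.append(
                SymbolSequence(subject_id, f"trial{k:03d}", text, alphabet)
            )
    return SequenceTable(tuple(sequences), alphabet)


def write_benchmark(
    dataset: BenchmarkDataset, tsv_path: str | Path, json_path: str | Path
) -> None:
    """Write a benchmark dataset as TSV plus a ground-truth JSON sidecar."""
    write_sequences(tsv_path, dataset.sequences())
    spec = dataset.spec
    truth = {
        "spec": {
            "orders": list(spec.orders),
            "models_per_order": spec.models_per_order,
            "sequences_per_order": spec.sequences_per_order,
            "length_range": list(spec.length_range),
            "burn_in": spec.burn_in,
            "master_seed": spec.master_seed,
            "exclusion_halfwidth": spec.exclusion_halfwidth,
        },
        "groups": [
            {
                "subject_id": g.sequences[0].subject_id,
                "true_order": g.order,
                "params": [float(p) for p in g.model.params],
                "n_sequences": len(g.sequences),
            }
            for g in dataset.groups
        ],
    }
    Path(json_path).write_text(json.dumps(truth, indent=2), encoding="utf-8")


def write_estimates_json(path: str | Path, estimates, extra: dict | None = None):
    """Serialize per-subject order estimates (plus run settings) to JSON."""
    payload = {
        "subjects": {e.subject_id: e.to_dict() for e in estimates},
    }
    if extra:
        payload["run"] = extra
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return payload


def _fmt(value, digits=3):
    if value is None:
        return "-"
    return f"{value:.{digits}f}"


def estimates_markdown(payload: dict) -> str:
    """Markdown report of evidences, decibans, categories and MLE matrices."""
    lines = ["# Markov order estimates", ""]
    lines.append(
        "| subject | order | log evidence | deciban vs order 0 | category |"
    )
    lines.append("|---|---|---|---|---|")
    for subject, res in payload["subjects"].items():
        for order_key in sorted(res["evidences"], key=int):
            ev = res["evidences"][order_key]
            db = res["decibans"][order_key]
            cat = res["categories"].get(order_key, "(null model)")
            lines.append(
                f"| {subject} | {order_key} | {_fmt(ev['log_evidence'])} "
                f"| {_fmt(db, 2)} | {cat} |"
            )
    lines.append("")
    lines.append("| subject | selected order | warnings |")
    lines.append("|---|---|---|")
    for subject, res in payload["subjects"].items():
        warn = "; ".join(res["warnings"]) or "-"
        lines.append(f"| {subject} | {res['selected_order']} | {warn} |")
    lines.append("")
    for subject, res in payload["subjects"].items():
        mle = res.get("mle_transition_order1")
        if not mle:
            continue
        lines.append(f"## {subject}: first-order MLE transition matrix")
        lines.append("")
        lines.append("| from \\ to | L | R |")
        lines.append("|---|---|---|")
        for label, row in zip(("L", "R"), mle["matrix"]):
            cells = " | ".join(_fmt(v) for v in row)
            lines.append(f"| {label} | {cells} |")
        lines.append("")
    return "\n".join(lines)
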