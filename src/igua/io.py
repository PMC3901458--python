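"""Readers and writers: clone FASTA input and the report bundle.

Reports: ``ua.fasta`` (modal UA), ``posterior.tsv`` (per-position posterior
and probable error), ``segments.tsv`` (segment posteriors), ``summary.json``
(junction summary, mu posterior, totals), ``tree.nwk``, and
``alignment_view.txt`` (queries over the modal UA, dots marking matches).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .inference import UAResult
from .phylo import to_newick

SCHEMA_VERSION = 1


class InputError(ValueError):
    """Raised for malformed input files."""


def read_clone_fasta(path: str | Path) -> dict[str, str]:
    """Read the clonal query set; uppercased, U->T, order preserved."""
    path = Path(path)
    sequences: dict[str, str] = {}
    bad: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise InputError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if set(seq) - set("ACGT"):
            bad.append(rec.id)
            continue
        sequences[rec.id] = seq
    if bad:
        raise InputError(
            f"{path}: records with non-ACGT characters (IUPAC ambiguity codes "
            f"are not supported): {bad}"
        )
    if not sequences:
        raise InputError(f"{path}: no FASTA records")
    return sequences


def write_fasta(path: str | Path, records: dict[str, str], width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def alignment_view(result: UAResult, width: int = 100) -> str:
    """Text alignment: queries (dots = match to the UA), modal UA, segments."""
    ua = result.modal_ua
    rows: list[tuple[str, str]] = []
    for qid, row in result.alignment.rows().items():
        dotted = "".join(
            "." if q == u and q != "-" else q for q, u in zip(row, ua)
        )
        rows.append((qid, dotted))
    rows.append(("UA", ua))
    for key in ("v", "d", "j"):
        entry = result.junction_summary.get(key)
        if not entry:
            continue
        a, b = entry["columns"]
        if b < a:
            continue
        track = [" "] * len(ua)
        track[a : b + 1] = list(ua[a : b + 1])
        rows.append((entry["segment_id"], "".join(track)))
    name_w = max(len(name) for name, _ in rows) + 2
    blocks: list[str] = []
    for start in range(0, len(ua), width):
        chunk = [
            f"{name:<{name_w}}{row[start:start + width]}" for name, row in rows
        ]
        ruler = f"{'':<{name_w}}{start + 1}"
        blocks.append("\n".join([ruler] + chunk))
    return "\n\n".join(blocks) + "\n"


def write_report(result: UAResult, outdir: str | Path) -> dict[str, Path]:
    """Write the full report bundle; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["ua"] = outdir / "ua.fasta"
    write_fasta(paths["ua"], {"UA": result.modal_ua})

    paths["posterior"] = outdir / "posterior.tsv"
    with paths["posterior"].open("w") as fh:
        fh.write("position\tP_A\tP_C\tP_G\tP_T\tprobable_error\n")
        for i, (row, err) in enumerate(
            zip(result.position_posterior.values, result.probable_error), start=1
        ):
            vals = "\t".join(f"{v:.6g}" for v in row)
            fh.write(f"{i}\t{vals}\t{err:.6g}\n")

    paths["segments"] = outdir / "segments.tsv"
    with paths["segments"].open("w") as fh:
        fh.write("role\tsegment_id\tposterior\n")
        for role, post in result.segment_posteriors.items():
            for sid, p in sorted(post.items(), key=lambda kv: -kv[1]):
                fh.write(f"{role}\t{sid}\t{p:.6g}\n")

    paths["summary"] = outdir / "summary.json"
    summary = {
        "schema": SCHEMA_VERSION,
        "modal_ua": result.modal_ua,
        "junction": result.junction_summary,
        "total_probable_error": result.total_probable_error,
        "mutation_frequency_percent": result.mutation_frequency,
        "mu_grid": list(map(float, result.mu_posterior.values)),
        "mu_posterior": list(map(float, result.mu_posterior.posterior)),
        "mu_mean": float(
            np.dot(result.mu_posterior.values, result.mu_posterior.posterior)
        ),
        "iterations": result.iterations,
        "converged": result.converged,
        "n_queries": result.alignment.n_queries,
        "alignment_length": result.alignment.length,
    }
    paths["summary"].write_text(json.dumps(summary, indent=2) + "\n")

    paths["tree"] = outdir / "tree.nwk"
    paths["tree"].write_text(to_newick(result.final_tree) + "\n")

    paths["view"] = outdir / "alignment_view.txt"
    paths["view"].write_text(alignment_view(result))
    return paths
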