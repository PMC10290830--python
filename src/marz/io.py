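"""Readers and writers for the formats the pipeline touches.

Sites come in as FASTA or one-sequence-per-line lists; promoters as FASTA
with truth intervals in BED (0-based half-open); matrices, catalogs, RZ
tables and hit lists go out as TSV; gapped PWMs can be exported in MEME
minimal motif format for cross-checks with external scanners.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrices import (
    ALPHABET,
    Background,
    CountMatrix,
    ProbabilityMatrix,
    SiteAlignment,
    WeightMatrix,
)
from .scanner import PromoterRecord, ScanHit


def read_sites(path: str | Path, fmt: str | None = None, label: str = "") -> SiteAlignment:
    """Load an aligned site list (``fasta`` or one-per-``line``).

    The format is sniffed from the first character when not given.  Ragged
    lengths or non-ACGT letters raise with the offending line named.
    """
    path = Path(path)
    text = path.read_text()
    if fmt is None:
        fmt = "fasta" if text.lstrip().startswith(">") else "line"
    if fmt == "fasta":
        sites = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
        if not sites:
            raise ValueError(f"no FASTA records in {path}")
        return SiteAlignment(sites, label=label or path.stem)
    if fmt != "line":
        raise ValueError(f"unknown site format {fmt!r}")
    sites = []
    length = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip().upper()
        if not line:
            continue
        if set(line) - set(ALPHABET):
            raise ValueError(f"{path}:{lineno}: non-ACGT characters in {line!r}")
        if length is None:
            length = len(line)
        elif len(line) != length:
            raise ValueError(
                f"{path}:{lineno}: length {len(line)} differs from {length}"
            )
        sites.append(line)
    if not sites:
        raise ValueError(f"no sites found in {path}")
    return SiteAlignment(sites, label=label or path.stem)


def write_sites(alignment: SiteAlignment, path: str | Path) -> None:
    Path(path).write_text("\n".join(alignment.sites) + "\n")


def read_promoters(
    fasta_path: str | Path, truth_path: str | Path | None = None
) -> list[PromoterRecord]:
    """FASTA promoters, optionally joined with BED truth intervals by id."""
    records = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    truths: dict[str, tuple[int, int]] = {}
    if truth_path is not None:
        for lineno, raw in enumerate(Path(truth_path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{truth_path}:{lineno}: need >= 3 BED fields")
            name, start, end = fields[0], int(fields[1]), int(fields[2])
            if name not in records:
                raise ValueError(
                    f"{truth_path}:{lineno}: id {name!r} absent from FASTA"
                )
            if end - start != 6:
                warnings.warn(
                    f"{truth_path}:{lineno}: truth interval length "
                    f"{end - start} != 6; accepted, overlap rule still applies",
                    stacklevel=2,
                )
            truths[name] = (start, end)
    return [
        PromoterRecord(id=name, sequence=seq, truth_interval=truths.get(name))
        for name, seq in records.items()
    ]


def write_promoters(records: list[PromoterRecord], fasta_path: str | Path,
                    truth_path: str | Path | None = None) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    if truth_path is not None:
        lines = [
            f"{r.id}\t{r.truth_interval[0]}\t{r.truth_interval[1]}"
            for r in records
            if r.truth_interval is not None
        ]
        Path(truth_path).write_text("\n".join(lines) + "\n")


def write_matrix(
    matrix: CountMatrix | ProbabilityMatrix | WeightMatrix, path: str | Path
) -> None:
    """TSV matrix (rows A,C,G,T; 1-based position columns) with a provenance
    header recording pseudocount / log base where applicable."""
    header = ["# marz matrix export"]
    if isinstance(matrix, CountMatrix):
        header.append(f"# kind=counts pseudocount={matrix.pseudocount:g}")
    elif isinstance(matrix, WeightMatrix):
        model = matrix.model.pattern if matrix.model else "full"
        header.append(
            f"# kind=log-odds log_base={matrix.log_base:g} model={model} "
            f"background={','.join(f'{p:g}' for p in matrix.background.probs)}"
        )
    else:
        header.append("# kind=probabilities")
    body = matrix.to_frame().to_csv(sep="\t")
    Path(path).write_text("\n".join(header) + "\n" + body)


def read_matrix_values(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_meme_motif(
    prob: ProbabilityMatrix,
    path: str | Path,
    name: str = "motif",
    background: Background | None = None,
    nsites: int | None = None,
) -> None:
    """MEME minimal motif format export of a (gapped) probability matrix.

    Ignored columns should already be background-filled by the caller when
    exporting a gapped model.
    """
    background = background or Background()
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: +",
        "",
        "Background letter frequencies",
        " ".join(
            f"{letter} {p:.6f}" for letter, p in zip(ALPHABET, background.probs)
        ),
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {prob.width} "
        + (f"nsites= {nsites}" if nsites else ""),
    ]
    for j in range(prob.width):
        lines.append(" ".join(f"{prob.values[i, j]:.6f}" for i in range(4)))
    Path(path).write_text("\n".join(lines).rstrip() + "\n")


def write_hits(hits: list[ScanHit], path: str | Path, width: int = 6) -> None:
    """BED-like TSV of scan hits (id, start, end, score, p_value)."""
    frame = pd.DataFrame(
        [
            dict(
                id=h.promoter_id,
                start=h.start,
                end=h.start + width,
                score=h.score,
                p_value=h.p_value,
            )
            for h in hits
        ],
        columns=["id", "start", "end", "score", "p_value"],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, config: dict) -> None:
    """Record run parameters (including the seed) so a run is re-executable."""
    import marz

    payload = dict(config)
    payload["marz_version"] = marz.__version__
    payload["numpy_version"] = np.__version__
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
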