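"""Readers and writers for FASTA/Stockholm inputs and the package's TSV formats."""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .core import ALPHABET, N_AA, ProfileMatrix, SequenceRecord, sanitize_residues
from .scan import ScanHit

logger = logging.getLogger(__name__)

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr|[a-z]+)\|([^|]+)\|\S*")


def _parse_id(raw_id: str) -> str:
    """UniProt-style ``db|ACC|NAME`` headers yield the accession; else the token."""
    m = _UNIPROT_HEADER.match(raw_id)
    return m.group(1) if m else raw_id


def _dedupe_ids(records: list[SequenceRecord]) -> list[SequenceRecord]:
    seen: dict[str, int] = {}
    out = []
    for rec in records:
        if rec.id in seen:
            seen[rec.id] += 1
            new_id = f"{rec.id}__{seen[rec.id]}"
            logger.warning("duplicate id %s renamed to %s", rec.id, new_id)
            rec = SequenceRecord(
                id=new_id, residues=rec.residues,
                description=rec.description, source=rec.source,
            )
        else:
            seen[rec.id] = 0
        out.append(rec)
    return out


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Load a (possibly gapped) FASTA file into sanitized records."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = sanitize_residues(str(rec.seq))
        if not residues:
            logger.warning("record %s empty after sanitization; dropped", rec.id)
            continue
        records.append(
            SequenceRecord(
                id=_parse_id(rec.id),
                residues=residues,
                description=rec.description.partition(" ")[2],
                source=str(path),
            )
        )
    if not records:
        raise ValueError(f"no usable sequence records in {path}")
    return _dedupe_ids(records)


def read_alignment(path: str | Path) -> list[SequenceRecord]:
    """Load a Stockholm or gapped-FASTA alignment, stripping gap columns."""
    path = Path(path)
    errors = []
    for fmt in ("stockholm", "fasta"):
        try:
            alignment = AlignIO.read(str(path), fmt)
            break
        except Exception as exc:  # malformed for this parser; try the next
            errors.append(f"{fmt}: {exc}")
    else:
        raise ValueError(
            f"could not parse {path} as an alignment ({'; '.join(errors)})"
        )
    records = []
    for rec in alignment:
        residues = sanitize_residues(str(rec.seq))
        if not residues:
            logger.warning("record %s empty after sanitization; dropped", rec.id)
            continue
        records.append(
            SequenceRecord(
                id=_parse_id(rec.id),
                residues=residues,
                description=rec.description if rec.description != "<unknown description>" else "",
                source=str(path),
            )
        )
    if not records:
        raise ValueError(f"no usable sequence records in {path}")
    return _dedupe_ids(records)


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# --- profile matrix TSV ---------------------------------------------------


def write_matrix(P: ProfileMatrix, path: str | Path) -> None:
    """Serialize a profile matrix; ``repr(float)`` guarantees bit-exact reload."""
    prov = P.provenance
    with open(path, "w") as fh:
        fh.write(f"#k={P.k}\n")
        fh.write(f"#M={P.M}\n")
        fh.write(f"#mode={P.mode}\n")
        fh.write(f"#seed={prov.get('seed', '')}\n")
        fh.write(f"#source={prov.get('source', '')}\n")
        fh.write("pos\t" + "\t".join(str(i) for i in range(1, P.k + 1)) + "\n")
        for j, aa in enumerate(ALPHABET):
            fh.write(aa + "\t" + "\t".join(repr(float(v)) for v in P.probs[j]) + "\n")


def read_matrix(path: str | Path) -> ProfileMatrix:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: dict[str, list[float]] = {}
    k = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
                continue
            fields = line.split("\t")
            if fields[0] == "pos":
                k = len(fields) - 1
                continue
            aa = fields[0]
            if aa not in ALPHABET:
                raise ValueError(f"{path}:{lineno}: unexpected row label {aa!r}")
            try:
                rows[aa] = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric entry ({exc})") from None
            if k is not None and len(rows[aa]) != k:
                raise ValueError(
                    f"{path}:{lineno}: expected {k} columns, got {len(rows[aa])}"
                )
    if len(rows) != N_AA:
        raise ValueError(
            f"{path}: expected {N_AA} residue rows, found {len(rows)}"
        )
    probs = np.array([rows[aa] for aa in ALPHABET])
    provenance = {}
    if meta.get("seed"):
        provenance["seed"] = int(meta["seed"])
    if meta.get("source"):
        provenance["source"] = meta["source"]
    return ProfileMatrix(
        k=int(meta["k"]),
        M=int(meta["M"]),
        probs=probs,
        mode=meta.get("mode", "paper"),
        provenance=provenance,
    )


# --- scan hits TSV --------------------------------------------------------

HIT_COLUMNS = [
    "rank", "protein_id", "description", "kmer", "start_1based",
    "phi", "log10_phi", "outlier_3iqr", "outlier_ref5", "duplicate_of",
]


def hits_to_frame(hits: list[ScanHit]) -> pd.DataFrame:
    rows = [
        {
            "rank": h.rank,
            "protein_id": h.protein_id,
            "description": h.description,
            "kmer": h.kmer_text,
            "start_1based": h.start_1based,
            "phi": h.phi,
            "log10_phi": h.log10_phi,
            "outlier_3iqr": h.outlier.get("iqr3", False),
            "outlier_ref5": h.outlier.get("ref5", False),
            "duplicate_of": h.duplicate_of or "",
        }
        for h in sorted(hits, key=lambda h: h.rank or 0)
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits(hits: list[ScanHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False, float_format="%.6e")


def read_hits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


# --- run manifest ---------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance of one command invocation, written next to its outputs."""

    command: str
    config: dict
    seed: int | None = None
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    version: str = ""
    timestamp: str = ""

    @classmethod
    def create(
        cls, command: str, config: dict, seed: int | None, input_paths: list[str | Path]
    ) -> "RunManifest":
        from . import __version__

        digests = {}
        for p in input_paths:
            h = hashlib.sha256()
            with open(p, "rb") as fh:
                for chunk in iter(lambda: fh.read(1 << 20), b""):
                    h.update(chunk)
            digests[str(p)] = h.hexdigest()
        return cls(
            command=command,
            config=config,
            seed=seed,
            inputs=digests,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")
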