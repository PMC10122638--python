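"""Readers and writers for the pipeline's plain-text formats.

Canonical tabular dialect: tab-separated, header row, UTF-8, '.' decimal.
Coordinates travel as BED6 plus an annotation-id column. Linear junction
counts live in one TSV with a ``side`` column (donor/acceptor blocks).
FASTA goes through Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .circquant import CircCandidate, FormatError, JunctionCountSet

__all__ = [
    "write_counts",
    "read_counts",
    "write_candidates_bed",
    "read_candidates_bed",
    "read_fasta",
    "write_fasta",
    "write_json",
]


def write_counts(jcs: JunctionCountSet, bsj_path, linear_path, meta_path) -> None:
    jcs.bsj.rename_axis("candidate_id").to_csv(bsj_path, sep="\t")
    donor = jcs.donor_linear.copy()
    donor.insert(0, "side", "donor")
    acceptor = jcs.acceptor_linear.copy()
    acceptor.insert(0, "side", "acceptor")
    pd.concat([donor, acceptor]).rename_axis("candidate_id").to_csv(
        linear_path, sep="\t"
    )
    jcs.samples.to_csv(meta_path, sep="\t")


def read_counts(
    bsj_path, linear_path, meta_path, candidates: list[CircCandidate] | None = None
) -> JunctionCountSet:
    """Read count TSVs back into a validated JunctionCountSet.

    Sample columns must match metadata rows exactly; mismatches are
    reported by name. When no candidate list is supplied, loci are parsed
    from the ``chrom:start-end:strand`` candidate ids.
    """
    bsj = pd.read_csv(bsj_path, sep="\t", index_col="candidate_id")
    linear = pd.read_csv(linear_path, sep="\t", index_col="candidate_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")

    sample_cols = [c for c in bsj.columns]
    missing = set(sample_cols) ^ set(meta.index)
    if missing:
        raise FormatError(f"sample mismatch between counts and metadata: {sorted(missing)}")
    donor = linear[linear["side"] == "donor"].drop(columns="side")
    acceptor = linear[linear["side"] == "acceptor"].drop(columns="side")
    for name, mat in (("bsj", bsj), ("donor", donor), ("acceptor", acceptor)):
        neg = mat.lt(0)
        if neg.any().any():
            col = neg.any().idxmax()
            row = neg[col].idxmax()
            raise FormatError(f"negative count in {name} at {row}/{col}")

    if candidates is None:
        candidates = [_candidate_from_id(i) for i in bsj.index]
    order = meta.index.tolist()
    ids = [c.id for c in candidates]
    mats = [bsj.loc[ids, order], donor.loc[ids, order], acceptor.loc[ids, order]]
    for m in mats:
        m.index.name = None
    return JunctionCountSet(
        candidates=candidates,
        samples=meta,
        bsj=mats[0],
        donor_linear=mats[1],
        acceptor_linear=mats[2],
    )


def _candidate_from_id(cand_id: str) -> CircCandidate:
    try:
        chrom, span, strand = cand_id.rsplit(":", 2)
        start, end = span.split("-")
        return CircCandidate(chrom=chrom, start=int(start), end=int(end), strand=strand)
    except (ValueError, FormatError) as exc:
        raise FormatError(f"cannot parse candidate id {cand_id!r}") from exc


def write_candidates_bed(candidates: list[CircCandidate], path) -> None:
    """BED6 + annotation id in column 7 (0-based half-open)."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.id}\t0\t{c.strand}"
                f"\t{c.annotation_id or '.'}\n"
            )


def read_candidates_bed(path) -> list[CircCandidate]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"BED line with {len(fields)} fields: {line!r}")
            annot = fields[6] if len(fields) > 6 and fields[6] != "." else None
            out.append(
                CircCandidate(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5],
                    annotation_id=annot,
                )
            )
    return out


def read_fasta(path, rna_to_dna: bool = False) -> list[tuple[str, str]]:
    """(id, sequence) pairs, sequences upper-cased; optional U->T."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rna_to_dna:
            seq = seq.replace("U", "T")
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records],
        str(path),
        "fasta",
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
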