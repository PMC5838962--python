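"""Reading and writing the plain-text formats used across the pipeline.

FASTA goes through Biopython.  LTR/domain annotations are accepted as
BED6 (name column ``ltr5`` / ``ltr3`` / ``domain:NAME``), GFF3 (types
``long_terminal_repeat`` with an ``ltr=5prime|3prime`` attribute, or any
other type treated as a domain) or a simple TSV.  A TSV sidecar maps
te_id to superfamily and family name.  Hits can be dumped as BED6, GFF3
or TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scanner import PQSHit
from .te import Superfamily, TERecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_te_set",
    "write_te_set",
    "write_hits_tsv",
    "write_hits_bed",
    "write_hits_gff3",
    "read_counts_tsv",
    "read_plate_tsv",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences of a (multi-record) FASTA file keyed by record id."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_annotation(path: Path):
    """Yield (te_id, kind, start, end, name) with 0-based half-open coords.

    kind is "ltr5", "ltr3" or "domain".
    """
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 9 and not fields[3].isalpha():
                # GFF3: 1-based inclusive coordinates
                te_id, _src, ftype, start, end, *_rest, attrs = fields
                attrs = _parse_gff3_attributes(attrs)
                s, e = int(start) - 1, int(end)
                if ftype.lower() in {"long_terminal_repeat", "ltr", "pqs"}:
                    which = attrs.get("ltr", attrs.get("Name", ""))
                    kind = "ltr5" if "5" in which else "ltr3"
                    yield te_id, kind, s, e, which
                else:
                    yield te_id, "domain", s, e, attrs.get("Name", ftype)
            else:
                # BED-like: 0-based half-open, name column says what it is
                te_id, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "ltr5"
                if name.startswith("ltr5"):
                    yield te_id, "ltr5", start, end, name
                elif name.startswith("ltr3"):
                    yield te_id, "ltr3", start, end, name
                else:
                    yield te_id, "domain", start, end, name.removeprefix("domain:")


def _read_sidecar(path: Path) -> dict[str, tuple[Superfamily, str]]:
    meta: dict[str, tuple[Superfamily, str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "te_id":
                continue
            te_id, superfamily = row[0], row[1]
            family = row[2] if len(row) > 2 else ""
            meta[te_id] = (Superfamily(superfamily), family)
    return meta


def read_te_set(
    fasta_path: str | Path,
    annotation_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> list[TERecord]:
    """Load a TE family set from FASTA + LTR annotation (+ optional sidecar).

    Every annotated te_id must occur in the FASTA; intervals are validated
    against sequence bounds.  Records lacking LTR annotation are kept with
    empty LTR intervals (``has_ltrs`` is False).
    """
    seqs = read_fasta(fasta_path)
    ann: dict[str, dict] = {te_id: {"domains": []} for te_id in seqs}
    for te_id, kind, s, e, name in _read_annotation(Path(annotation_path)):
        if te_id not in seqs:
            raise ValueError(f"annotation references unknown te_id {te_id!r}")
        if not (0 <= s < e <= len(seqs[te_id])):
            raise ValueError(
                f"{te_id}: interval ({s}, {e}) out of bounds "
                f"(length {len(seqs[te_id])})"
            )
        if kind == "domain":
            ann[te_id]["domains"].append((name, (s, e)))
        else:
            ann[te_id][kind] = (s, e)
    meta = _read_sidecar(Path(sidecar_path)) if sidecar_path else {}
    records = []
    for te_id, seq in seqs.items():
        sf, family = meta.get(te_id, (Superfamily.OTHER, ""))
        a = ann[te_id]
        records.append(
            TERecord(
                te_id=te_id,
                superfamily=sf,
                sequence=seq,
                family_name=family,
                ltr5=a.get("ltr5"),
                ltr3=a.get("ltr3"),
                domains=tuple(a["domains"]),
            )
        )
    return records


def write_te_set(
    records: Iterable[TERecord],
    fasta_path: str | Path,
    bed_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    """Write a TE set as FASTA + BED6 LTR annotation + TSV sidecar."""
    records = list(records)
    write_fasta({r.te_id: r.sequence for r in records}, fasta_path)
    with open(bed_path, "w") as fh:
        for r in records:
            for kind, iv in (("ltr5", r.ltr5), ("ltr3", r.ltr3)):
                if iv is not None:
                    fh.write(f"{r.te_id}\t{iv[0]}\t{iv[1]}\t{kind}\t0\t+\n")
            for name, (s, e) in r.domains:
                fh.write(f"{r.te_id}\t{s}\t{e}\tdomain:{name}\t0\t+\n")
    with open(sidecar_path, "w") as fh:
        fh.write("te_id\tsuperfamily\tfamily_name\n")
        for r in records:
            fh.write(f"{r.te_id}\t{r.superfamily.value}\t{r.family_name}\n")


def write_hits_tsv(hits: Iterable[PQSHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "seq_id\tstart\tend\tstrand\ttetrads\tn_bulged\tscore\t"
            "loop1\tloop2\tloop3\trun_lengths\n"
        )
        for h in hits:
            runs = ",".join(str(r.g_count) for r in h.runs)
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.tetrads}\t"
                f"{h.n_bulged}\t{h.score:g}\t{h.loops[0]}\t{h.loops[1]}\t"
                f"{h.loops[2]}\t{runs}\n"
            )


def write_hits_bed(hits: Iterable[PQSHit], path: str | Path) -> None:
    """BED6; name = seq_id:rank, score column clipped to [0, 1000]."""
    with open(path, "w") as fh:
        for rank, h in enumerate(hits, start=1):
            score = min(int(h.score), 1000)
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.seq_id}:{rank}\t"
                f"{score}\t{h.strand}\n"
            )


def write_hits_gff3(hits: Iterable[PQSHit], path: str | Path) -> None:
    """GFF3 (1-based inclusive) with tetrads/loops/tier attributes."""
    from .scanner import classify_score

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hits:
            loops = ",".join(str(x) for x in h.loops)
            tier = classify_score(h).value
            fh.write(
                f"{h.seq_id}\tg4ltr\tPQS\t{h.start + 1}\t{h.end}\t"
                f"{h.score:g}\t{h.strand}\t.\t"
                f"tetrads={h.tetrads};loops={loops};tier={tier}\n"
            )


def read_counts_tsv(path: str | Path):
    """TE-by-sample count matrix from TSV (first column te_id)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col=0)


def read_plate_tsv(path: str | Path):
    """Plate readings, one per row, into a list of PlateReading."""
    import pandas as pd

    from .assay import PlateReading

    df = pd.read_csv(path, sep="\t")
    return [PlateReading(**row) for row in df.to_dict(orient="records")]
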