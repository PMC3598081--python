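"""TSV/FASTA output helpers with reproducibility headers.

Every pipeline artifact starts with a comment line naming the effective
config hash and seed, so a run can be traced back to its configuration; no
timestamps are written, keeping identical runs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    header_note: str | None = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    seqio_write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq) for rec in parse(str(path), "fasta")}


def write_bed(intervals, name_prefix: str, path: str | Path, chrom: str = "seq") -> None:
    """CGI intervals as BED (0-based half-open)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals, start=1):
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{name_prefix}_{i}\n")
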