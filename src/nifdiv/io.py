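"""File input/output: FASTA, truth tables, isotope and time-course CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .isara import IsotopeSample, TimeCourse
from .records import ReadRecord, ReadTruth, ReferenceSequence


def write_fasta(records: list[tuple[str, str]], path, wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_reads_fasta(reads: list[ReadRecord], path) -> None:
    write_fasta([(r.id, r.dna) for r in reads], path)


def read_reads_fasta(path, site: str = "synthetic") -> list[ReadRecord]:
    return [ReadRecord(id=rid, dna=seq, site=site) for rid, seq in read_fasta(path)]


def write_references_fasta(refs: list[ReferenceSequence], path) -> None:
    write_fasta([(f"{r.id} {r.isozyme}", r.dna) for r in refs], path)


def write_truth_table(reads: list[ReadRecord], path) -> None:
    rows = []
    for r in reads:
        t = r.truth or ReadTruth(source_ref_id="")
        pa, pb = t.chimera_parents or ("", "")
        rows.append(
            dict(read_id=r.id, source_ref_id=t.source_ref_id,
                 is_chimera=t.is_chimera, parent_a=pa, parent_b=pb,
                 is_internal_standard=t.is_internal_standard,
                 n_errors=t.n_errors)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> dict[str, ReadTruth]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = {}
    for row in df.itertuples(index=False):
        parents = (row.parent_a, row.parent_b) if row.parent_a else None
        out[row.read_id] = ReadTruth(
            source_ref_id=row.source_ref_id,
            is_chimera=bool(row.is_chimera),
            chimera_parents=parents,
            is_internal_standard=bool(row.is_internal_standard),
            n_errors=int(row.n_errors),
        )
    return out


def write_isotope_csv(samples: list[IsotopeSample], path) -> None:
    pd.DataFrame(
        [
            dict(sample_id=s.sample_id, replicate=s.replicate,
                 delta13C_acetylene=s.delta13C_acetylene,
                 delta13C_ethylene=s.delta13C_ethylene)
            for s in samples
        ]
    ).to_csv(path, index=False)


def read_isotope_csv(path) -> list[IsotopeSample]:
    df = pd.read_csv(path)
    return [
        IsotopeSample(
            sample_id=str(r.sample_id),
            delta13C_acetylene=float(r.delta13C_acetylene),
            delta13C_ethylene=float(r.delta13C_ethylene),
            replicate=int(r.replicate),
        )
        for r in df.itertuples(index=False)
    ]


def write_timecourse_csv(tcs: list[TimeCourse], path) -> None:
    rows = [
        dict(sample_id=tc.sample_id, time_h=t, ethylene_ppmv=e)
        for tc in tcs
        for t, e in zip(tc.times, tc.ethylene)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_timecourse_csv(path) -> list[TimeCourse]:
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_h")
        out.append(
            TimeCourse(
                sample_id=str(sid),
                times=grp["time_h"].tolist(),
                ethylene=grp["ethylene_ppmv"].tolist(),
            )
        )
    return out


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(o):
    if hasattr(o, "tolist"):
        return o.tolist()
    if hasattr(o, "__dict__"):
        return o.__dict__
    return str(o)
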