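"""Readers and writers for the package's on-disk formats.

FASTA/FASTQ go through Biopython.  Collapsed FASTA uses the fastx-style
``>name_xCOUNT`` header convention.  Coordinates are 1-based inclusive in
every written table; internal 0-based coordinates are converted here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .degradome import DegradomeTag
from .phasing import PhasLocus, PhasiRNA
from .srna import PositionProfile, SmallRNARead, normalize_rpm
from .synthetic import GroundTruth, PlantedLocus, PlantedPhasiRNA, PlantedTarget


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_collapsed_fasta(path, counts: Mapping[str, int], prefix: str = "r") -> None:
    """Write unique sequences with counts encoded as ``>r<i>_x<count>``."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(sorted(counts.items()), start=1):
            fh.write(f">{prefix}{i}_x{count}\n{seq}\n")


def read_collapsed_fasta(path) -> list[SmallRNARead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = 1
        if "_x" in rec.id:
            tail = rec.id.rsplit("_x", 1)[1]
            if tail.isdigit():
                count = int(tail)
        reads.append(SmallRNARead(str(rec.seq), count))
    return reads


def read_fastq(path) -> list[SmallRNARead]:
    """Read FASTQ and collapse identical sequences."""
    acc: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        s = str(rec.seq)
        acc[s] = acc.get(s, 0) + 1
    return [SmallRNARead(s, c) for s, c in acc.items()]


def write_tags_tsv(path, tags: Sequence[DegradomeTag]) -> None:
    rows = [
        {
            "transcript_id": t.transcript_id,
            "position": t.position,
            "count": t.count,
            "sequence": t.sequence,
        }
        for t in tags
    ]
    pd.DataFrame(rows, columns=["transcript_id", "position", "count", "sequence"]).to_csv(
        path, sep="\t", index=False
    )


def read_tags_tsv(path) -> list[DegradomeTag]:
    df = pd.read_csv(path, sep="\t")
    return [
        DegradomeTag(
            transcript_id=str(r.transcript_id),
            position=int(r.position),
            count=int(r.count),
            sequence=str(getattr(r, "sequence", "")),
        )
        for r in df.itertuples(index=False)
    ]


def write_profile_tsv(path, profile: PositionProfile) -> None:
    """BED-like per-position table: ref, start, end, strand, length, count, RPM."""
    rows = []
    for (ref, strand, pos, length), count in sorted(profile.counts.items()):
        rpm = (
            normalize_rpm(count, profile.library_total)
            if profile.library_total > 0
            else 0.0
        )
        rows.append(
            {
                "reference_id": ref,
                "start": pos + 1,
                "end": pos + 1,
                "strand": strand,
                "length": length,
                "count": count,
                "rpm": rpm,
            }
        )
    pd.DataFrame(
        rows,
        columns=["reference_id", "start", "end", "strand", "length", "count", "rpm"],
    ).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path) -> PositionProfile:
    prof = PositionProfile()
    df = pd.read_csv(path, sep="\t")
    for r in df.itertuples(index=False):
        prof.add(str(r.reference_id), str(r.strand), int(r.start) - 1, int(r.length), float(r.count))
    prof.library_total = float(df["count"].sum()) if len(df) else 0.0
    return prof


def write_loci_gff3(path, loci: Sequence[PhasLocus]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for L in loci:
            attrs = [
                f"ID={L.locus_id}",
                f"period={L.period}",
                f"register={L.register}",
                f"phase_score={L.max_score:.3f}",
            ]
            if L.trigger is not None:
                attrs.append(
                    f"trigger={L.trigger.mirna}"
                    f";trigger_score={L.trigger.score:.2f}"
                    f";trigger_register_consistent={str(L.trigger.register_consistent).lower()}"
                )
            fh.write(
                "\t".join(
                    [
                        L.reference_id,
                        "phasiscan",
                        "siRNA_locus",
                        str(L.start + 1),
                        str(L.end),
                        f"{L.max_score:.3f}",
                        L.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def loci_table(loci: Sequence[PhasLocus]) -> pd.DataFrame:
    rows = []
    for L in loci:
        rows.append(
            {
                "locus_id": L.locus_id,
                "reference_id": L.reference_id,
                "start": L.start + 1,
                "end": L.end,
                "period": L.period,
                "register": L.register,
                "strand": L.strand,
                "phase_score": L.max_score,
                "k": L.max_k,
                "trigger": L.trigger.mirna if L.trigger else "",
                "trigger_score": L.trigger.score if L.trigger else "",
                "trigger_cleavage": (
                    L.trigger.cleavage_pos0 + 1
                    if L.trigger and L.trigger.cleavage_pos0 is not None
                    else ""
                ),
                "trigger_register_consistent": (
                    L.trigger.register_consistent if L.trigger else ""
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "reference_id",
            "start",
            "end",
            "period",
            "register",
            "strand",
            "phase_score",
            "k",
            "trigger",
            "trigger_score",
            "trigger_cleavage",
            "trigger_register_consistent",
        ],
    )


def phasirna_table(phasirnas: Sequence[PhasiRNA]) -> pd.DataFrame:
    lib_names = sorted({lib for x in phasirnas for lib in x.abundances})
    rows = []
    for x in phasirnas:
        row = {
            "name": x.name,
            "locus_id": x.locus_id,
            "offset": x.offset,
            "strand": x.strand,
            "position": x.position + 1,
            "sequence": x.sequence,
            "count": x.count,
        }
        for lib in lib_names:
            row[f"count_{lib}"] = x.abundances.get(lib, 0.0)
        rows.append(row)
    cols = ["name", "locus_id", "offset", "strand", "position", "sequence", "count"]
    cols += [f"count_{lib}" for lib in lib_names]
    return pd.DataFrame(rows, columns=cols)


def write_truth(outdir, truth: GroundTruth) -> None:
    outdir = Path(outdir)
    pd.DataFrame(
        [
            {
                "ref_id": L.ref_id,
                "period": L.period,
                "trigger": L.trigger_name,
                "trigger_start": L.trigger_start + 1,
                "trigger_end": L.trigger_end,
                "cleavage_pos": L.cleavage_pos0 + 1,
                "register": L.register,
                "plus_positions": ",".join(str(p + 1) for p in L.plus_positions),
                "minus_positions": ",".join(str(p + 1) for p in L.minus_positions),
            }
            for L in truth.loci
        ]
    ).to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "ref_id": x.ref_id,
                "strand": x.strand,
                "position": x.position + 1,
                "period": x.period,
                "sequence": x.sequence,
                "forced_c": x.forced_c,
                "mean_wildtype": x.mean_wildtype,
                "mean_mutant": x.mean_mutant,
            }
            for x in truth.phasirnas
        ]
    ).to_csv(outdir / "truth_phasirnas.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "srna_sequence": t.srna_sequence,
                "source_ref": t.source_ref,
                "source_position": t.source_position + 1,
                "site_start": t.site_start0 + 1,
                "cleavage_site": t.cleavage_site,
                "validatable": t.validatable,
            }
            for t in truth.targets
        ]
    ).to_csv(outdir / "truth_targets.tsv", sep="\t", index=False)


def read_truth(outdir) -> GroundTruth:
    outdir = Path(outdir)
    truth = GroundTruth()
    loci = pd.read_csv(outdir / "truth_loci.tsv", sep="\t")
    for r in loci.itertuples(index=False):
        truth.loci.append(
            PlantedLocus(
                ref_id=str(r.ref_id),
                period=int(r.period),
                trigger_name=str(r.trigger),
                trigger_start=int(r.trigger_start) - 1,
                trigger_end=int(r.trigger_end),
                cleavage_pos0=int(r.cleavage_pos) - 1,
                register=int(r.register),
                plus_positions=[int(p) - 1 for p in str(r.plus_positions).split(",")],
                minus_positions=[int(p) - 1 for p in str(r.minus_positions).split(",")],
            )
        )
    phas = pd.read_csv(outdir / "truth_phasirnas.tsv", sep="\t")
    for r in phas.itertuples(index=False):
        truth.phasirnas.append(
            PlantedPhasiRNA(
                ref_id=str(r.ref_id),
                strand=str(r.strand),
                position=int(r.position) - 1,
                period=int(r.period),
                sequence=str(r.sequence),
                forced_c=bool(r.forced_c),
                mean_wildtype=float(r.mean_wildtype),
                mean_mutant=float(r.mean_mutant),
            )
        )
    targets = pd.read_csv(outdir / "truth_targets.tsv", sep="\t")
    for r in targets.itertuples(index=False):
        truth.targets.append(
            PlantedTarget(
                transcript_id=str(r.transcript_id),
                srna_sequence=str(r.srna_sequence),
                source_ref=str(r.source_ref),
                source_position=int(r.source_position) - 1,
                site_start0=int(r.site_start) - 1,
                cleavage_pos0=int(r.cleavage_site) - 1,
                validatable=bool(r.validatable),
            )
        )
    return truth
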