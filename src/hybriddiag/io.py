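"""Readers and writers for the standard formats at the package boundary.

Internal coordinates are 0-based half-open; VCF positions are written
1-based and BED intervals 0-based half-open, per their dialects.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .blocks import PhaseBlock
from .simulate import ChecklistTable, DiploidIndividual, ParentalPanel, Pileup

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_panel_fasta",
    "write_pileup_tsv",
    "read_pileup_tsv",
    "write_blocks_bed",
    "write_tracts_bed",
    "write_phased_vcf",
    "read_phased_vcf_blocks",
    "write_checklists_csv",
    "read_checklists_csv",
]


def write_fasta(path, records: dict[str, str]) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_panel_fasta(path, panel: ParentalPanel) -> None:
    write_fasta(path, {panel.label_a: panel.seq_a, panel.label_b: panel.seq_b})


def write_pileup_tsv(path, pileup: Pileup, scaffold: str = "scaffold_1") -> None:
    """One row per read: scaffold, 0-based position, base, BQ, MQ.
    Zero-depth positions are written once with base '*' and depth 0."""
    with open(path, "w") as fh:
        fh.write("scaffold\tpos\tdepth\tbase\tbq\tmq\n")
        for i, column in enumerate(pileup.columns):
            pos = pileup.start + i
            if not column:
                fh.write(f"{scaffold}\t{pos}\t0\t*\t0\t0\n")
                continue
            for base, bq, mq in column:
                fh.write(f"{scaffold}\t{pos}\t{len(column)}\t{base}\t{bq}\t{mq}\n")


def read_pileup_tsv(path) -> Pileup:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError("empty pileup file")
    start = int(df["pos"].min())
    end = int(df["pos"].max()) + 1
    columns: list[list[tuple[str, int, int]]] = [[] for _ in range(end - start)]
    for row in df.itertuples(index=False):
        if row.base == "*":
            continue
        columns[int(row.pos) - start].append((str(row.base), int(row.bq), int(row.mq)))
    return Pileup(start=start, columns=columns)


def write_blocks_bed(path, blocks: Sequence[PhaseBlock]) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.scaffold}\t{b.start}\t{b.end}\tn_variants={b.n_variants}\n")


def write_tracts_bed(path, ind: DiploidIndividual, scaffold: str = "scaffold_1") -> None:
    with open(path, "w") as fh:
        for hap_idx, tracts in enumerate(ind.truth_tracts, start=1):
            for start, end, lineage in tracts:
                fh.write(f"{scaffold}\t{start}\t{end}\thap{hap_idx}:{lineage}\n")


def write_phased_vcf(
    path,
    ind: DiploidIndividual,
    blocks: Sequence[PhaseBlock],
    reference: str,
    scaffold: str = "scaffold_1",
) -> None:
    """Minimal phased single-sample VCF: GT phased within blocks, PS set to
    the 1-based block start (the usual phase-set convention)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={scaffold},length={len(reference)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + ind.sample_id + "\n"
        )
        for b in blocks:
            ps = b.start + 1
            for pos in b.variant_positions:
                ref = reference[pos]
                a1 = b.hap1_seq[pos - b.start]
                a2 = b.hap2_seq[pos - b.start]
                alts = [a for a in dict.fromkeys([a1, a2]) if a != ref and a != "N"]
                if not alts:
                    continue
                code = {ref: "0"}
                for k, a in enumerate(alts, start=1):
                    code[a] = str(k)
                gt = f"{code.get(a1, '.')}|{code.get(a2, '.')}"
                fh.write(
                    f"{scaffold}\t{pos + 1}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT:PS\t{gt}:{ps}\n"
                )


def read_phased_vcf_blocks(path, reference: str) -> list[PhaseBlock]:
    """Reconstruct phase blocks from a phased single-sample VCF (PS-tagged),
    filling non-variant positions from the reference."""
    from cyvcf2 import VCF

    groups: dict[tuple[str, int], list[tuple[int, str, str]]] = {}
    for variant in VCF(str(path)):
        g = variant.genotypes[0]  # [allele1, allele2, phased]
        if len(g) < 3 or not g[2]:
            continue
        alleles = [variant.REF] + variant.ALT
        a1 = alleles[g[0]] if g[0] >= 0 else "N"
        a2 = alleles[g[1]] if g[1] >= 0 else "N"
        ps_arr = variant.format("PS")
        ps = int(ps_arr[0][0]) if ps_arr is not None else 0
        groups.setdefault((variant.CHROM, ps), []).append((variant.POS - 1, a1, a2))
    blocks = []
    for (chrom, _ps), entries in sorted(groups.items(), key=lambda kv: kv[0][1]):
        entries.sort()
        start = entries[0][0]
        end = entries[-1][0] + 1
        h1 = list(reference[start:end])
        h2 = list(reference[start:end])
        for pos, a1, a2 in entries:
            h1[pos - start] = a1
            h2[pos - start] = a2
        blocks.append(
            PhaseBlock(
                scaffold=chrom,
                start=start,
                end=end,
                variant_positions=[p for p, _, _ in entries],
                hap1_seq="".join(h1),
                hap2_seq="".join(h2),
            )
        )
    return blocks


def write_checklists_csv(path, table: ChecklistTable) -> None:
    df = table.records.copy()
    df["species"] = df["species"].apply(";".join)
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_checklists_csv(path) -> ChecklistTable:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    df["complete"] = df["complete"].astype(bool)
    df["species"] = df["species"].fillna("").apply(
        lambda s: tuple(x for x in str(s).split(";") if x)
    )
    return ChecklistTable(records=df)
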