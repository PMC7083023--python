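"""Call-set serialization: BEDPE (primary, 0-based half-open) and VCF 4.2.

BEDPE columns: chrom1, bp1 start/end, chrom2(=body chromosome), bp2
start/end, name=sv_type, score=n_split_molecules, then insertion-locus
interval (chrom/start/end or dots), rp_support, depth, filter_status.
The VCF mirrors the same calls with symbolic alleles; translocations are
encoded as breakend pairs carrying the insertion locus in INFO.
"""
from __future__ import annotations

import pandas as pd
import pysam

from .graph import SVCall

BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "name", "score", "ins_chrom", "ins_start", "ins_end",
                 "rp_support", "depth", "filter"]


def calls_to_dataframe(calls: list[SVCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "chrom1": c.chrom1, "start1": c.bp1[0], "end1": c.bp1[1],
            "chrom2": c.chrom1, "start2": c.bp2[0], "end2": c.bp2[1],
            "name": c.sv_type, "score": c.n_split_molecules,
            "ins_chrom": c.chrom2 if c.bp3 is not None else ".",
            "ins_start": c.bp3[0] if c.bp3 is not None else -1,
            "ins_end": c.bp3[1] if c.bp3 is not None else -1,
            "rp_support": c.rp_support,
            "depth": round(c.depth, 3) if c.depth is not None else -1.0,
            "filter": c.filter_status,
        })
    return pd.DataFrame(rows, columns=BEDPE_COLUMNS)


def write_bedpe(calls: list[SVCall], path) -> None:
    df = calls_to_dataframe(calls)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_bedpe(path) -> list[SVCall]:
    df = pd.read_csv(path, sep="\t", comment="#", names=BEDPE_COLUMNS,
                     dtype={"chrom1": str, "chrom2": str, "ins_chrom": str})
    calls = []
    for row in df.itertuples(index=False):
        has3 = row.ins_chrom != "." and row.ins_start >= 0
        calls.append(SVCall(
            sv_type=row.name, chrom1=row.chrom1,
            bp1=(int(row.start1), int(row.end1)),
            bp2=(int(row.start2), int(row.end2)),
            chrom2=row.ins_chrom if has3 else None,
            bp3=(int(row.ins_start), int(row.ins_end)) if has3 else None,
            n_split_molecules=int(row.score), rp_support=int(row.rp_support),
            depth=None if row.depth < 0 else float(row.depth),
            filter_status=row.filter))
    return calls


def _vcf_header(chrom_lengths: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=int(length))
    for line in [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of the variant">',
        '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS">',
        '##INFO=<ID=CIEND,Number=2,Type=Integer,Description="Confidence interval around END">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Insertion-locus chromosome">',
        '##INFO=<ID=POS2,Number=1,Type=Integer,Description="Insertion-locus position (1-based)">',
        '##INFO=<ID=CIINS,Number=2,Type=Integer,Description="Confidence interval around POS2">',
        '##INFO=<ID=DUPORI,Number=1,Type=String,Description="Duplication orientation">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Distinct supporting candidate splits">',
        '##INFO=<ID=RSUP,Number=1,Type=Integer,Description="Supporting discordant read pairs">',
        '##INFO=<ID=MDEPTH,Number=1,Type=Float,Description="Mean molecule depth over the source interval">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##FILTER=<ID=depth_fail,Description="Molecule depth inconsistent with the SV type">',
        '##FILTER=<ID=no_depth,Description="No depth profile over the call interval">',
        '##FILTER=<ID=min_support_fail,Description="Too few split molecules or barcodes">',
        '##FILTER=<ID=duplicate,Description="Merged into an overlapping better-supported call">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##ALT=<ID=DUP,Description="Interspersed segmental duplication">',
    ]:
        header.add_line(line)
    return header


def write_vcf(calls: list[SVCall], chrom_lengths: dict[str, int], path) -> None:
    """Write calls as VCF 4.2 (1-based); TRA becomes a breakend pair."""
    header = _vcf_header(chrom_lengths)
    vf = pysam.VariantFile(str(path), "w", header=header)
    for k, c in enumerate(calls):
        body = c.body
        flt = c.filter_status if c.filter_status != "PASS" else "PASS"
        common = dict(SUPPORT=c.n_split_molecules, RSUP=c.rp_support)
        if c.depth is not None:
            common["MDEPTH"] = round(c.depth, 3)
        if c.sv_type == "TRA":
            for tag, pos, mate in (("A", body[0], "B"), ("B", body[1], "A")):
                rec = vf.new_record(contig=c.chrom1, start=pos,
                                    alleles=("N", f"N[{c.chrom2}:{c.insertion_point + 1}["),
                                    id=f"TRA_{k}_{tag}", filter=flt)
                rec.info["SVTYPE"] = "BND"
                rec.info["MATEID"] = f"TRA_{k}_{mate}"
                rec.info["CHR2"] = c.chrom2
                rec.info["POS2"] = c.insertion_point + 1
                rec.info["CIINS"] = (c.bp3[0] - c.insertion_point,
                                     c.bp3[1] - c.insertion_point)
                for key, val in common.items():
                    rec.info[key] = val
                vf.write(rec)
            continue
        alt = "DUP" if c.sv_type.startswith("DUP") else c.sv_type
        rec = vf.new_record(contig=c.chrom1, start=body[0],
                            alleles=("N", f"<{alt}>"), id=f"{alt}_{k}",
                            filter=flt, stop=body[1])
        rec.info["SVTYPE"] = alt
        rec.info["CIPOS"] = (c.bp1[0] - body[0], c.bp1[1] - body[0])
        rec.info["CIEND"] = (c.bp2[0] - body[1], c.bp2[1] - body[1])
        if c.sv_type.startswith("DUP"):
            rec.info["CHR2"] = c.chrom2
            rec.info["POS2"] = c.insertion_point + 1
            rec.info["CIINS"] = (c.bp3[0] - c.insertion_point,
                                 c.bp3[1] - c.insertion_point)
            rec.info["DUPORI"] = "direct" if c.sv_type == "DUP_DIRECT" \
                else "inverted"
        for key, val in common.items():
            rec.info[key] = val
        rec.stop = body[1]  # set last: INFO assignment can rederive END
        vf.write(rec)
    vf.close()
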