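"""Readers and writers for the interchange formats.

Coordinates are 0-based half-open internally (BED native; GFF3 and VCF are
converted on read).  All tables are tab-separated with a header line;
floats are written at 6 significant digits.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ValidationError
from .haplotypes import HaplotypeMatrix

log = logging.getLogger("sweepset")

FLOAT_FMT = "%.6g"


# -- gene annotation ---------------------------------------------------------


def load_genes(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Load a GeneTable skeleton from BED or GFF3.

    BED columns chrom/start/end/name are used directly (0-based half-open);
    for GFF3 the transcript extremes of each gene are computed on read and
    1-based inclusive coordinates converted.  Focal labels and
    disease-variant counts default to False/0 and are attached afterwards
    with :func:`apply_focal_labels`.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    if fmt == "bed":
        rows = _parse_bed(path)
    elif fmt == "gff3":
        rows = _parse_gff3(path)
    else:
        raise ValueError(f"unknown gene annotation format {fmt!r}")
    if not rows:
        log.warning("gene annotation %s is empty", path)
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "span_start", "span_end"])
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id in {path}: {dup}")
    genes["center"] = (genes["span_start"] + genes["span_end"]) / 2.0
    genes["is_focal"] = False
    genes["n_disease_variants"] = 0
    return genes.sort_values(["chrom", "center"], kind="mergesort").reset_index(drop=True)


def _parse_bed(path: Path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}:{ln}: BED line needs >= 4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValidationError(f"{path}:{ln}: non-integer coordinates") from e
            if start >= end:
                raise ValidationError(f"{path}:{ln}: start must be < end")
            rows.append((parts[3], parts[0], start, end))
    return rows


def _parse_gff3(path: Path) -> list[tuple]:
    # transcript extremes per gene: min start / max end over mRNA/transcript
    # children; genes without annotated transcripts fall back to their own span
    gene_span: dict[str, list] = {}
    tx_span: dict[str, list] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValidationError(f"{path}:{ln}: GFF3 line needs 9 columns")
            chrom, _src, ftype, start_s, end_s = parts[0], parts[1], parts[2], parts[3], parts[4]
            try:
                start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
            except ValueError as e:
                raise ValidationError(f"{path}:{ln}: non-integer coordinates") from e
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if kv and "=" in kv
            )
            if ftype == "gene":
                gid = attrs.get("ID") or attrs.get("gene_id")
                if gid is None:
                    raise ValidationError(f"{path}:{ln}: gene feature without ID")
                gene_span[gid] = [chrom, start, end]
            elif ftype in ("mRNA", "transcript"):
                parent = attrs.get("Parent")
                if parent is None:
                    continue
                if parent in tx_span:
                    tx_span[parent][1] = min(tx_span[parent][1], start)
                    tx_span[parent][2] = max(tx_span[parent][2], end)
                else:
                    tx_span[parent] = [chrom, start, end]
    rows = []
    for gid, (chrom, start, end) in gene_span.items():
        if gid in tx_span:
            chrom, start, end = tx_span[gid]
        rows.append((gid, chrom, start, end))
    return rows


def apply_focal_labels(genes: pd.DataFrame, focal: pd.DataFrame) -> pd.DataFrame:
    """Attach focal-set labels (and optional disease-variant counts)."""
    out = genes.copy()
    out["is_focal"] = out["gene_id"].isin(set(focal["gene_id"]))
    if "n_disease_variants" in focal.columns:
        counts = focal.set_index("gene_id")["n_disease_variants"]
        out["n_disease_variants"] = out["gene_id"].map(counts).fillna(0).astype(int)
    unknown = set(focal["gene_id"]) - set(out["gene_id"])
    if unknown:
        log.warning("%d focal gene ids not present in the annotation", len(unknown))
    return out


def load_focal_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValidationError(f"{path}: focal list needs a gene_id column")
    return df


# -- confounders & scores ----------------------------------------------------


def load_confounders(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValidationError(f"{path}: confounder table needs a gene_id column")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValidationError(f"{path}: missing values in confounder columns {bad}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def load_scores(path: str | Path) -> pd.DataFrame:
    """Read a per-SNP or per-gene score TSV (round-trip of write_table)."""
    return pd.read_csv(path, sep="\t")


def write_control_sets(sets: list[np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join(map(str, s)) + "\n")


def load_control_sets(path: str | Path) -> list[np.ndarray]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(np.array(line.split("\t")))
    return out


def write_json_report(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


# -- genetic map & VCF -------------------------------------------------------


def load_genetic_map(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Genetic map TSV with columns chrom, pos_bp, cM -> per-chrom arrays."""
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "pos_bp", "cM"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path}: genetic map needs columns {sorted(need)}")
    out = {}
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values("pos_bp")
        out[str(chrom)] = (
            sub["pos_bp"].to_numpy(dtype=np.int64),
            sub["cM"].to_numpy(dtype=float),
        )
    return out


def interpolate_cm(positions_bp: np.ndarray, chrom_map: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    pos, cm = chrom_map
    return np.interp(positions_bp, pos, cm)


def load_vcf(
    path: str | Path,
    genetic_map: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    default_cm_per_mb: float = 1.0,
) -> dict[str, HaplotypeMatrix]:
    """Load phased, ancestrally polarized haplotypes from a VCF.

    Requires fully phased diploid GT fields (an unphased genotype is an
    error naming the first offending record) and an AA (ancestral allele)
    INFO tag; sites without usable AA, non-SNPs and multiallelic sites are
    dropped with a logged count.  Derived allele coding: if AA equals REF
    the ALT is derived; if AA equals ALT the coding is flipped.  cM
    positions come from the genetic map (linear interpolation) or from a
    uniform ``default_cm_per_mb`` when no map is given.
    """
    from cyvcf2 import VCF

    per_chrom: dict[str, list] = {}
    dropped = 0
    vcf = VCF(str(path))
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            dropped += 1
            continue
        aa = var.INFO.get("AA")
        if aa is None:
            dropped += 1
            continue
        aa = str(aa).split("|")[0].strip().upper()
        if aa == var.REF.upper():
            flip = False
        elif aa == var.ALT[0].upper():
            flip = True
        else:
            dropped += 1
            continue
        gts = np.array(var.genotypes)  # (n_samples, 3): a, b, phased
        if gts.shape[1] < 3 or not gts[:, 2].all():
            raise ValidationError(
                f"unphased genotype at {var.CHROM}:{var.POS}; pipeline requires phased data"
            )
        if (gts[:, :2] < 0).any():
            raise ValidationError(
                f"missing genotype at {var.CHROM}:{var.POS}; pipeline requires complete data"
            )
        hap = gts[:, :2].reshape(-1).astype(np.int8)
        if flip:
            hap = 1 - hap
        per_chrom.setdefault(var.CHROM, []).append((var.POS - 1, hap))
    if dropped:
        log.info("dropped %d sites without usable ancestral polarity or non-biallelic", dropped)
    out = {}
    for chrom, sites in per_chrom.items():
        sites.sort(key=lambda t: t[0])
        # drop duplicate positions (keep first)
        seen = set()
        uniq = []
        for pos, hap in sites:
            if pos in seen:
                continue
            seen.add(pos)
            uniq.append((pos, hap))
        positions = np.array([p for p, _ in uniq], dtype=np.int64)
        alleles = np.stack([h for _, h in uniq], axis=1)
        if genetic_map is not None and chrom in genetic_map:
            cm = interpolate_cm(positions, genetic_map[chrom])
        else:
            cm = positions * default_cm_per_mb / 1e6
        out[chrom] = HaplotypeMatrix(alleles=alleles, positions_bp=positions, positions_cM=cm)
    return out


def write_vcf(hap: HaplotypeMatrix, path: str | Path, chrom: str = "1") -> None:
    """Write a HaplotypeMatrix as a minimal phased VCF (AA tag = REF)."""
    if hap.n_haplotypes % 2:
        raise ValueError("need an even number of haplotypes to write diploid samples")
    n_samples = hap.n_haplotypes // 2
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"s{i}" for i in range(n_samples))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(hap.n_sites):
            col = hap.alleles[:, j]
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samples))
            fh.write(
                f"{chrom}\t{hap.positions_bp[j] + 1}\t{hap.site_ids[j]}\tA\tG\t.\t.\tAA=A\tGT\t{gts}\n"
            )


def write_genetic_map(hap: HaplotypeMatrix, path: str | Path, chrom: str = "1") -> None:
    df = pd.DataFrame(
        {"chrom": chrom, "pos_bp": hap.positions_bp, "cM": hap.positions_cM}
    )
    write_table(df, path)


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    bed = genes[["chrom", "span_start", "span_end", "gene_id"]]
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_focal_list(genes: pd.DataFrame, path: str | Path) -> None:
    focal = genes.loc[genes["is_focal"], ["gene_id", "n_disease_variants"]]
    write_table(focal, path)
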