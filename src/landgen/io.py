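"""Readers/writers for the interchange formats the pipeline touches.

Genepop is the canonical SNP-matrix interchange; a GT-only VCF subset and ESRI
ASCII grids (land cover) are also supported. All readers validate the type
invariants of the shared data model on the way in.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    WATER,
    FormatError,
    GenotypeMatrix,
    LandscapeRaster,
    PloidyError,
    SampleFrame,
)

__all__ = [
    "read_genepop",
    "write_genepop",
    "read_vcf_lite",
    "write_vcf_lite",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_coords_csv",
    "write_coords_csv",
]


# ---------------------------------------------------------------- Genepop

def read_genepop(path: str | Path) -> tuple[GenotypeMatrix, SampleFrame]:
    """Parse a diploid Genepop 4.x file into dosages.

    Allele codes may be 2- or 3-digit but must be consistent within the file.
    The lexically smaller allele code observed at a locus becomes the reference
    allele; dosages count the other (alt) allele. Returns the matrix and a
    SampleFrame carrying only pop labels (Genepop has no coordinates).
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise FormatError("truncated Genepop file")
    # title line, then locus names until first 'pop'
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if not loci:
        raise FormatError("empty loci header")
    if i == len(lines):
        raise FormatError("no 'pop' blocks found")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[str]] = []
    pop_idx = 0
    width: int | None = None
    for line in lines[i:]:
        s = line.strip()
        if not s:
            continue
        if s.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in s:
            raise FormatError(f"malformed individual line: {s!r}")
        name, geno = s.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise FormatError(
                f"individual {name.strip()!r} has {len(fields)} genotypes, "
                f"expected {len(loci)}"
            )
        for f in fields:
            if len(f) not in (4, 6):
                raise FormatError(f"bad genotype field {f!r}")
            w = len(f) // 2
            if width is None:
                width = w
            elif w != width:
                raise FormatError("mixed allele-code widths in file")
        ids.append(name.strip())
        pops.append(f"pop{pop_idx}")
        rows.append(fields)

    assert width is not None
    n, L = len(ids), len(loci)
    G = np.zeros((n, L), dtype=np.int8)
    for j, locus in enumerate(loci):
        alleles = sorted(
            {f[k : k + width] for f in (r[j] for r in rows) for k in (0, width)}
        )
        if any(a == "0" * width for a in alleles):
            raise FormatError(f"missing allele code at locus {locus}")
        if len(alleles) > 2:
            raise PloidyError(f"locus {locus} has {len(alleles)} alleles (>2)")
        ref = alleles[0]
        for r, f in enumerate(rows):
            g = f[j]
            G[r, j] = (g[:width] != ref) + (g[width:] != ref)
    gm = GenotypeMatrix(ids, list(loci), G)
    # Genepop carries no coordinates: the frame holds pop labels only
    sf = SampleFrame(pd.DataFrame({"id": ids, "pop": pops}))
    return gm, sf


def write_genepop(
    gm: GenotypeMatrix, pops: np.ndarray, path: str | Path, title: str = "landgen export"
) -> None:
    """Write dosages as 2-digit Genepop ('01' = reference, '02' = alt)."""
    pops = np.asarray(pops)
    code = {0: "0101", 1: "0102", 2: "0202"}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        fh.write("\n".join(gm.loci) + "\n")
        for pop in pd.unique(pops):
            fh.write("pop\n")
            for i in np.flatnonzero(pops == pop):
                genos = " ".join(code[int(g)] for g in gm.G[i])
                fh.write(f"{gm.individuals[i]} , {genos}\n")


# ---------------------------------------------------------------- VCF (lite)

def read_vcf_lite(path: str | Path) -> GenotypeMatrix:
    """Read a GT-only biallelic VCF 4.x subset.

    Multi-allelic records are skipped with a warning; missing genotypes are an
    error because the pipeline requires complete matrices.
    """
    samples: list[str] = []
    loci: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise FormatError(f"short VCF record: {line!r}")
            chrom, pos, vid, _ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt:
                skipped += 1
                warnings.warn(
                    f"skipping multi-allelic record {chrom}:{pos}", stacklevel=2
                )
                continue
            fmt = parts[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise FormatError(f"record {chrom}:{pos} lacks GT") from None
            dosages = []
            for field in parts[9:]:
                gt = field.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    raise FormatError(
                        f"missing genotype at {chrom}:{pos}; matrix must be complete"
                    )
                a, b = (int(x) for x in gt.split("/"))
                if a > 1 or b > 1:
                    raise PloidyError(f"allele index >1 at biallelic {chrom}:{pos}")
                dosages.append(a + b)
            loci.append(vid if vid not in (".", "") else f"{chrom}_{pos}")
            rows.append(np.array(dosages, dtype=np.int8))
    if not rows:
        raise FormatError("no biallelic records in VCF")
    G = np.stack(rows, axis=1)
    return GenotypeMatrix(samples, loci, G)


def write_vcf_lite(gm: GenotypeMatrix, path: str | Path) -> None:
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=landgen\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals)
            + "\n"
        )
        for j, locus in enumerate(gm.loci):
            gts = "\t".join(gt_code[int(g)] for g in gm.G[:, j])
            fh.write(f"1\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------- ESRI grid

def read_ascii_grid(path: str | Path) -> LandscapeRaster:
    """ESRI ASCII grid of land-cover codes; NODATA cells become water."""
    lines = Path(path).read_text().split("\n")
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            body_start = i
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise FormatError(f"missing ASCII-grid header field {key}")
    nodata = header.get("nodata_value", -9999)
    values = []
    for line in lines[body_start:]:
        if line.strip():
            values.extend(int(float(v)) for v in line.split())
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if len(values) != ncols * nrows:
        raise FormatError(
            f"grid body has {len(values)} cells, header says {ncols * nrows}"
        )
    grid = np.array(values).reshape(nrows, ncols)
    grid[grid == int(nodata)] = WATER
    return LandscapeRaster(
        classes=grid,
        cellsize_km=header["cellsize"],
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
    )


def write_ascii_grid(raster: LandscapeRaster, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner}\n")
        fh.write(f"yllcorner {raster.yllcorner}\n")
        fh.write(f"cellsize {raster.cellsize_km}\n")
        fh.write("NODATA_value -9999\n")
        for row in raster.classes:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------- coords CSV

def read_coords_csv(path: str | Path) -> SampleFrame:
    return SampleFrame(pd.read_csv(path, dtype={"id": str, "pop": str}))


def write_coords_csv(sf: SampleFrame, path: str | Path) -> None:
    sf.table.to_csv(path, index=False)
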