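"""Genotype matrix I/O and post-calling filters.

Two on-disk formats are supported:

* VCF 4.2, biallelic SNP records with a GT field.  Phasing is ignored and
  half-calls are treated as missing; multi-allelic records are skipped with a
  logged count.  Individual labels (species, tree, caste) travel in header
  ``##SAMPLE`` lines.
* a TSV dialect: one row per individual with columns ``id``, ``species``,
  ``tree``, ``caste``, ``excluded``, then one two-character genotype column
  per locus (``AA``/``AB``/``BB``/``--``).

Filtering reproduces a standard RADseq post-calling cascade: individuals with
low SNP coverage are culled first (coverage measured over loci passing a
preliminary presence screen), then loci are kept only if they satisfy a
per-species presence cutoff, an observed-heterozygosity ceiling, and a
minor-allele-frequency floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (CALL_TO_STR, HET, HOM_ALT, HOM_REF, MISSING, STR_TO_CALL,
                     GenotypeMatrix)

logger = logging.getLogger(__name__)

LABEL_COLUMNS = ["id", "species", "tree", "caste", "excluded"]


@dataclass
class FilterSettings:
    """Locus and individual filter thresholds.

    ``presence_r`` maps species name to the fraction of that species'
    individuals in which a locus must be called; ``default_r`` covers species
    not listed.  ``r_prelim`` is the presence screen used only to define the
    locus set over which individual coverage is measured.
    """

    presence_r: dict = field(default_factory=dict)
    default_r: float = 0.5
    max_het: float = 0.5
    min_maf: float = 0.02
    min_coverage: float = 0.2
    r_prelim: float = 0.5

    def __post_init__(self) -> None:
        vals = [self.default_r, self.max_het, self.r_prelim,
                *self.presence_r.values()]
        if any(not 0.0 < v <= 1.0 for v in vals):
            raise ValueError("rates must lie in (0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must lie in [0, 1]")

    def r_for(self, species: str) -> float:
        return self.presence_r.get(species, self.default_r)


# ---------------------------------------------------------------------------
# TSV dialect

def write_tsv(G: GenotypeMatrix, path) -> None:
    labels = G.labels_frame()
    geno = pd.DataFrame(
        np.vectorize(CALL_TO_STR.get)(G.calls), columns=list(G.loci))
    pd.concat([labels, geno], axis=1).to_csv(path, sep="\t", index=False)


def read_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"TSV lacks label columns {missing_cols}")
    if len(df) == 0:
        raise ValueError("TSV contains no individuals")
    loci = [c for c in df.columns if c not in LABEL_COLUMNS]
    geno = df[loci].to_numpy()
    bad = ~np.isin(geno, list(STR_TO_CALL))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"malformed genotype {geno[r, c]!r} at data line {r + 1}, "
            f"locus {loci[c]}")
    calls = np.vectorize(STR_TO_CALL.get)(geno).astype(np.int8)
    return GenotypeMatrix(
        calls=calls,
        ids=df["id"].to_numpy(dtype=object),
        species=df["species"].to_numpy(dtype=object),
        tree=df["tree"].to_numpy(dtype=object),
        caste=df["caste"].to_numpy(dtype=object),
        loci=np.array(loci, dtype=object),
        excluded=df["excluded"].map({"True": True, "False": False}).to_numpy(),
    )


# ---------------------------------------------------------------------------
# VCF

_GT_MAP = {
    "0/0": HOM_REF, "0|0": HOM_REF,
    "0/1": HET, "1/0": HET, "0|1": HET, "1|0": HET,
    "1/1": HOM_ALT, "1|1": HOM_ALT,
}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write biallelic SNP records with GT only; labels in ##SAMPLE lines."""
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for i, ind in enumerate(G.ids):
            fh.write(
                f"##SAMPLE=<ID={ind},Species={G.species[i]},Tree={G.tree[i]},"
                f"Caste={G.caste[i]},Excluded={int(G.excluded[i])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, G.ids)) + "\n")
        for j, locus in enumerate(G.loci):
            gts = "\t".join(gt_str[int(c)] for c in G.calls[:, j])
            fh.write(f"1\t{j + 1}\t{locus}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP GT calls via cyvcf2; multi-allelic records skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF contains no samples")
    meta = {s: {"Species": "unknown", "Tree": "unknown", "Caste": "worker",
                "Excluded": "0"} for s in samples}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##SAMPLE=<") and line.endswith(">"):
            fields = dict(kv.split("=", 1)
                          for kv in line[len("##SAMPLE=<"):-1].split(","))
            sid = fields.pop("ID", None)
            if sid in meta:
                meta[sid].update(fields)

    loci, rows = [], []
    n_skipped = 0
    for k, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        gts = rec.genotypes  # [allele1, allele2, phased] per sample
        row = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            row[i] = MISSING if (a < 0 or b < 0) else a + b
        rows.append(row)
        loci.append(rec.ID if rec.ID not in (None, ".")
                    else f"{rec.CHROM}:{rec.POS}")
    if n_skipped:
        logger.warning("skipped %d multi-allelic VCF record(s)", n_skipped)
    if not rows:
        raise ValueError("VCF contains no biallelic records")
    ids = np.array(samples, dtype=object)
    return GenotypeMatrix(
        calls=np.array(rows, dtype=np.int8).T,
        ids=ids,
        species=np.array([meta[s]["Species"] for s in samples], dtype=object),
        tree=np.array([meta[s]["Tree"] for s in samples], dtype=object),
        caste=np.array([meta[s]["Caste"] for s in samples], dtype=object),
        loci=np.array(loci, dtype=object),
        excluded=np.array([meta[s]["Excluded"] in ("1", "True")
                           for s in samples]),
    )


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Dispatch on format ('vcf' or 'tsv'; inferred from suffix if None)."""
    if format is None:
        format = "vcf" if str(path).endswith(".vcf") else "tsv"
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        return read_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(G: GenotypeMatrix, path, format: str | None = None) -> None:
    if format is None:
        format = "vcf" if str(path).endswith(".vcf") else "tsv"
    if format == "vcf":
        write_vcf(G, path)
    elif format == "tsv":
        write_tsv(G, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# statistics used by the filters

def observed_heterozygosity(G: GenotypeMatrix) -> np.ndarray:
    """Per-locus fraction of non-missing individuals called heterozygous.

    Loci with no non-missing call are undefined and returned as NaN, never
    as zero.
    """
    observed = G.calls != MISSING
    n_obs = observed.sum(axis=0)
    n_het = (G.calls == HET).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n_obs > 0, n_het / np.maximum(n_obs, 1), np.nan)
    return h


def _presence(G: GenotypeMatrix) -> np.ndarray:
    """Per-locus fraction of individuals with a call, per species minimum.

    The presence rule is per species ("present in at least r of the
    individuals in the species"); for a single-species matrix this is the
    plain per-locus call rate.
    """
    return (G.calls != MISSING).mean(axis=0)


def _minor_allele_frequency(G: GenotypeMatrix) -> np.ndarray:
    observed = G.calls != MISSING
    n_obs = observed.sum(axis=0)
    alt = np.where(observed, G.calls, 0).sum(axis=0)  # alt-allele count
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_obs > 0, alt / np.maximum(2 * n_obs, 1), np.nan)
    return np.minimum(p_alt, 1.0 - p_alt)


def filter_individuals(
    G: GenotypeMatrix, settings: FilterSettings
) -> GenotypeMatrix:
    """Cull individuals with SNP coverage below ``min_coverage``.

    Coverage is the fraction of non-missing calls over the loci passing a
    preliminary presence screen at ``r_prelim`` (computed per species).
    """
    keep = np.ones(G.n_individuals, dtype=bool)
    for sp in dict.fromkeys(G.species):
        rows = np.flatnonzero(G.species == sp)
        sub = G.take_individuals(rows)
        screened = _presence(sub) >= settings.r_prelim
        if not screened.any():
            continue  # no screenable loci; keep everyone in this species
        cov = (sub.calls[:, screened] != MISSING).mean(axis=1)
        keep[rows[cov < settings.min_coverage]] = False
    removed = list(G.ids[~keep])
    if removed:
        logger.info("removed %d low-coverage individual(s): %s",
                    len(removed), removed)
    if not keep.any():
        raise ValueError("all individuals removed by the coverage filter")
    return G.take_individuals(np.flatnonzero(keep))


def filter_loci(G: GenotypeMatrix, settings: FilterSettings) -> GenotypeMatrix:
    """Keep loci passing presence, heterozygosity, and MAF rules.

    A locus is kept iff, within every species present in the matrix, its
    call rate is >= that species' presence cutoff, and pooled within species
    its observed heterozygosity is <= ``max_het`` (strict ``>`` removes) and
    its minor allele frequency is >= ``min_maf``.  Locus order is preserved
    and per-rule removal counts are logged.
    """
    n_loci = G.n_loci
    pass_presence = np.ones(n_loci, dtype=bool)
    pass_het = np.ones(n_loci, dtype=bool)
    pass_maf = np.ones(n_loci, dtype=bool)
    for sp in dict.fromkeys(G.species):
        sub = G.subset_species(sp)
        r = settings.r_for(sp)
        pass_presence &= _presence(sub) >= r
        het = observed_heterozygosity(sub)
        with np.errstate(invalid="ignore"):
            pass_het &= ~(het > settings.max_het)  # NaN (all-missing) passes
            maf = _minor_allele_frequency(sub)
            pass_maf &= ~(maf < settings.min_maf)
    keep = pass_presence & pass_het & pass_maf
    logger.info(
        "locus filter: %d in, %d kept (%d failed presence, %d failed het, "
        "%d failed MAF)", n_loci, int(keep.sum()),
        int((~pass_presence).sum()), int((~pass_het).sum()),
        int((~pass_maf).sum()))
    if not keep.any():
        raise ValueError("no loci survive the locus filters")
    return G.take_loci(np.flatnonzero(keep))


def apply_filters(G: GenotypeMatrix, settings: FilterSettings
                  ) -> GenotypeMatrix:
    """Pipeline order: individual coverage cull first, then locus filters."""
    return filter_loci(filter_individuals(G, settings), settings)
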