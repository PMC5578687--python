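"""File formats and the end-to-end inference pipeline.

Genotypes are read from VCF (biallelic SNPs, GT field; cyvcf2) or PLINK
.ped/.map text.  Genetic positions come from the .map cM column (or VCF
positions), with a constant 1 cM/Mb fallback when the map column is empty -
the fallback is logged.  Pedigrees are written as PLINK .fam-style text
(FID IID PAT MAT SEX PHENO) extended with a SAMPLED column, plus a JSON
sidecar holding latent-node metadata and the composite-likelihood score
breakdown.  Parent id 0 denotes a missing parent, following the .fam
convention.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .anneal import AnnealConfig, multi_start
from .hmm import GenotypeMatrix, build_table, estimate_frequencies
from .pedigree import FEMALE, MALE, Pedigree
from .scoring import ScoreBreakdown, total_score
from .simulate import ld_prune

log = logging.getLogger("kinforest")

SEX_CODE = {MALE: "1", FEMALE: "2", None: "0"}
CODE_SEX = {"1": MALE, "2": FEMALE}


# ------------------------------------------------------------------ readers
def read_genotypes(path, fmt: Optional[str] = None,
                   map_path=None, error_rate: float = 0.01) -> GenotypeMatrix:
    """Read a biallelic-SNP dosage matrix from VCF or PLINK .ped/.map text.

    Non-biallelic or non-SNP records are skipped (count logged).  Allele
    frequencies are sample estimates with a pseudo-count; override them
    afterwards if a reference panel is available.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz") else "ped"
    if fmt == "vcf":
        gm = _read_vcf(path, error_rate)
    elif fmt == "ped":
        gm = _read_ped(path, map_path, error_rate)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if gm.L == 0:
        raise ValueError(f"{path}: no usable biallelic SNPs")
    return gm


def _read_vcf(path, error_rate) -> GenotypeMatrix:
    from cyvcf2 import VCF

    v = VCF(str(path), gts012=True)
    ids = list(v.samples)
    rows, cm, chrom, bp = [], [], [], []
    skipped = 0
    for rec in v:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        g = rec.gt_types  # 0=hom ref, 1=het, 2=hom alt (cyvcf2 gt012 order: 3=unknown)
        d = np.where(g == 3, -1, np.where(g == 2, 2, g)).astype(np.int8)
        rows.append(d)
        chrom.append(rec.CHROM)
        bp.append(rec.POS)
        cm.append(rec.POS * 1e-6)  # 1 cM/Mb fallback
    if skipped:
        log.info("skipped %d non-biallelic/non-SNP records", skipped)
    log.info("no genetic map in VCF: using 1 cM/Mb from physical positions")
    G = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(ids), 0), np.int8)
    freqs = _safe_freqs(G)
    keep = (freqs > 0) & (freqs < 1)
    return GenotypeMatrix(G[:, keep], freqs[keep], np.array(cm)[keep],
                          np.array(chrom)[keep], error_rate, ids,
                          bp=np.array(bp)[keep])


def _read_ped(path, map_path, error_rate) -> GenotypeMatrix:
    path = Path(path)
    if map_path is None:
        map_path = path.with_suffix(".map")
    chrom, cm, bp = [], [], []
    zero_cm = True
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        f = line.split()
        if not f:
            continue
        if len(f) < 4:
            raise ValueError(f"{map_path}:{ln}: expected 4 columns")
        chrom.append(f[0])
        cm.append(float(f[2]))
        bp.append(int(f[3]))
        if float(f[2]) != 0:
            zero_cm = False
    if zero_cm:
        cm = [b * 1e-6 for b in bp]
        log.info("empty cM column in %s: using 1 cM/Mb fallback", map_path)
    ids, sexes, rows = [], {}, []
    L = len(chrom)
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        f = line.split()
        if not f:
            continue
        if len(f) != 6 + 2 * L:
            raise ValueError(f"{path}:{ln}: expected {6 + 2 * L} fields, got {len(f)}")
        ids.append(f[1])
        if f[4] in CODE_SEX:
            sexes[f[1]] = CODE_SEX[f[4]]
        alleles = np.array(f[6:], dtype=object).reshape(L, 2)
        rows.append(alleles)
    # determine per-locus allele coding: count allele "2"/second-seen allele
    G = np.full((len(ids), L), -1, dtype=np.int8)
    A = np.stack(rows) if rows else np.zeros((0, L, 2), object)
    for l in range(L):
        col = A[:, l, :]
        obs = col[col != "0"]
        alleles = sorted(set(obs.tolist()))
        if len(alleles) > 2:
            raise ValueError(f"{path}: locus {l + 1} has >2 alleles")
        alt = alleles[-1] if alleles else "2"
        miss = (col == "0").any(axis=1)
        G[:, l] = np.where(miss, -1, (col == alt).sum(axis=1))
    freqs = _safe_freqs(G)
    keep = (freqs > 0) & (freqs < 1)
    if keep.sum() < L:
        log.info("dropped %d monomorphic loci", L - int(keep.sum()))
    return GenotypeMatrix(G[:, keep], freqs[keep], np.array(cm, float)[keep],
                          np.array(chrom)[keep], error_rate, ids, sex=sexes,
                          bp=np.array(bp)[keep])


def _safe_freqs(G) -> np.ndarray:
    return estimate_frequencies(G) if G.shape[1] else np.zeros(0)


# ------------------------------------------------------------------ writers
def write_ped(gm: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write PLINK .ped/.map text (alleles coded 1/2, missing 0)."""
    prefix = Path(prefix)
    pedp, mapp = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    with open(mapp, "w") as fh:
        for l in range(gm.L):
            b = int(gm.bp[l]) if gm.bp is not None else int(round(gm.cm[l] * 1e6))
            fh.write(f"{gm.chrom[l]} snp{l + 1} {gm.cm[l]:.6f} {b}\n")
    with open(pedp, "w") as fh:
        for k, sid in enumerate(gm.ids):
            sex = SEX_CODE.get(gm.sex.get(sid), "0")
            cells = [str(sid), str(sid), "0", "0", sex, "-9"]
            for g in gm.genotypes[k]:
                cells.extend({-1: ["0", "0"], 0: ["1", "1"],
                              1: ["1", "2"], 2: ["2", "2"]}[int(g)])
            fh.write(" ".join(cells) + "\n")
    return pedp, mapp


def write_vcf(gm: GenotypeMatrix, path) -> Path:
    path = Path(path)
    gtmap = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, gm.ids)) + "\n")
        for l in range(gm.L):
            pos = int(gm.bp[l]) if gm.bp is not None else int(round(gm.cm[l] * 1e6))
            row = [str(gm.chrom[l]), str(pos), f"snp{l + 1}", "A", "G",
                   ".", "PASS", ".", "GT"]
            row += [gtmap[int(g)] for g in gm.genotypes[:, l]]
            fh.write("\t".join(row) + "\n")
    return path


def write_pedigree(ped: Pedigree, score: Optional[ScoreBreakdown],
                   path_prefix) -> tuple[Path, Path]:
    """Write the extended .fam (FID IID PAT MAT SEX PHENO SAMPLED) plus the
    JSON sidecar with latent metadata and the score breakdown."""
    prefix = Path(path_prefix)
    famp = prefix.with_suffix(".fam")
    jsp = prefix.with_suffix(".json")
    comp_of = {}
    for k, comp in enumerate(sorted(ped.components(),
                                    key=lambda c: min(map(str, c)))):
        for v in comp:
            comp_of[v] = k + 1
    with open(famp, "w") as fh:
        for v in sorted(ped.parents, key=str):
            ps = list(ped.parents[v])
            pat = mat = "0"
            if ps:
                sx = [ped.sex.get(p) for p in ps]
                if len(ps) == 2:
                    if sx[0] == FEMALE or sx[1] == MALE:
                        ps = ps[::-1]
                    pat, mat = str(ps[0]), str(ps[1])
                else:
                    if sx[0] == FEMALE:
                        mat = str(ps[0])
                    else:
                        pat = str(ps[0])
            fh.write(f"F{comp_of[v]} {v} {pat} {mat} "
                     f"{SEX_CODE.get(ped.sex.get(v), '0')} -9 "
                     f"{1 if v in ped.sampled else 0}\n")
    side = {
        "latent": sorted(str(v) for v in ped.parents if v not in ped.sampled),
        "mz_pairs": sorted(sorted(map(str, p)) for p in ped.mz_pairs),
        "score": None if score is None else {
            "total_log_score": score.total_log_score,
            "q": score.q, "beta": score.beta, "lambda": score.lam,
            "per_component_logCL": {str(k): v for k, v in
                                    score.per_component_logCL.items()},
        },
    }
    jsp.write_text(json.dumps(side, indent=1))
    return famp, jsp


def read_pedigree(path_prefix) -> Pedigree:
    """Read the extended .fam (+ JSON sidecar if present) back."""
    prefix = Path(path_prefix)
    famp = prefix.with_suffix(".fam")
    parents, sex, sampled = {}, {}, []
    for ln, line in enumerate(famp.read_text().splitlines(), 1):
        f = line.split()
        if not f:
            continue
        if len(f) < 6:
            raise ValueError(f"{famp}:{ln}: expected >= 6 columns")
        iid, pat, mat = f[1], f[2], f[3]
        parents[iid] = tuple(p for p in (pat, mat) if p != "0")
        if f[4] in CODE_SEX:
            sex[iid] = CODE_SEX[f[4]]
        if len(f) >= 7 and f[6] == "1":
            sampled.append(iid)
    jsp = prefix.with_suffix(".json")
    mz = []
    if jsp.exists():
        side = json.loads(jsp.read_text())
        mz = [tuple(p) for p in side.get("mz_pairs", [])]
    return Pedigree(parents=parents, sex=sex, sampled=sampled, mz_pairs=mz)


# ----------------------------------------------------------------- pipeline
@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    geno_path: object = None
    fmt: Optional[str] = None
    map_path: object = None
    freq_path: object = None
    sex_path: object = None
    age_path: object = None
    r2: float = 0.05
    window_cm: float = 0.5
    anneal: AnnealConfig = field(default_factory=AnnealConfig)
    lam_choice: str = "n"  # "n", "n/2", or a float string
    out_prefix: object = "kinforest_out"
    error_rate: float = 0.01

    def resolve_lam(self, n: int) -> float:
        if self.lam_choice == "n":
            return float(n)
        if self.lam_choice == "n/2":
            return n / 2.0
        return float(self.lam_choice)


def full_pipeline(config: RunConfig,
                  gm: Optional[GenotypeMatrix] = None,
                  truth: Optional[Pedigree] = None) -> dict:
    """read -> frequency estimation -> prune -> table -> anneal -> write.

    Returns a dict with the inferred pedigree, score breakdown, per-run
    scores, and output paths.  Never mutates its input files.
    """
    t0 = time.time()
    if gm is None:
        gm = read_genotypes(config.geno_path, config.fmt, config.map_path,
                            config.error_rate)
    log.info("loaded %d individuals x %d markers", gm.n, gm.L)
    if config.sex_path is not None:
        for line in Path(config.sex_path).read_text().splitlines():
            f = line.split()
            if len(f) >= 2 and f[1] in ("M", "F", "1", "2"):
                gm.sex[f[0]] = {"1": "M", "2": "F"}.get(f[1], f[1])
    if config.age_path is not None:
        for line in Path(config.age_path).read_text().splitlines():
            f = line.split()
            if len(f) >= 2:
                gm.age[f[0]] = float(f[1])
    if config.freq_path is not None:
        freqs = np.loadtxt(config.freq_path)
        if len(freqs) != gm.L:
            raise ValueError("frequency file length mismatch")
        gm = GenotypeMatrix(gm.genotypes, freqs, gm.cm, gm.chrom,
                            gm.error_rate, gm.ids, gm.sex, gm.age, gm.bp)
    gm = ld_prune(gm, config.r2, config.window_cm)
    log.info("%d markers after LD pruning at r2=%g", gm.L, config.r2)
    table = build_table(gm)
    log.info("pairwise table built in %.1fs", time.time() - t0)
    cfg = AnnealConfig(**{**config.anneal.__dict__,
                          "lam": config.resolve_lam(gm.n)})
    ped, breakdown, scores = multi_start(table, cfg, sex=gm.sex, age=gm.age)
    log.info("best score %.3f over %d restarts", breakdown.total_log_score,
             len(scores))
    out = {"pedigree": ped, "score": breakdown, "run_scores": scores,
           "table": table}
    if config.out_prefix is not None:
        famp, jsp = write_pedigree(ped, breakdown, config.out_prefix)
        tsv = Path(config.out_prefix).with_suffix(".scores.tsv")
        with open(tsv, "w") as fh:
            fh.write("run\tscore\n")
            for k, s in enumerate(scores):
                fh.write(f"{k}\t{s:.6f}\n")
        out["paths"] = {"fam": famp, "json": jsp, "scores": tsv}
    if truth is not None:
        from .metrics import compare_pedigrees
        out["report"] = compare_pedigrees(ped, truth)
    return out
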