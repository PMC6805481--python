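"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: pedigree/phenotype/y_c tables as CSV,
genotypes as PLINK-style .ped/.map text or VCF (GT and DS fields; VCF
is read through cyvcf2), QTL regions as TSV (with a converter from a
GFF-like dialect), and relationship matrices as an id-indexed
lower-triangle text format plus an .npz container with an id header.
Unknown parents are coded 0; positions are 1-based inclusive bp.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DataError, GenotypePanel, Pedigree, RelationshipMatrix

PED_COLS = ["id", "sire", "dam", "sex", "birth_date", "population", "herd"]


# ---------------------------------------------------------------------------
# tables


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.table[PED_COLS].to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    t = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    missing = set(PED_COLS) - set(t.columns)
    if missing:
        raise DataError(f"pedigree file lacks columns {sorted(missing)}")
    return Pedigree(t)


def write_phenotypes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format="%.10g")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str, "litter": str, "herd": str})


def write_yc(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def read_yc(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str})


# ---------------------------------------------------------------------------
# PLINK-style text


def write_plink(panel: GenotypePanel, prefix) -> None:
    """.ped/.map pair; missing genotypes become '0 0'."""
    prefix = Path(prefix)
    mp = panel.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, r in mp.iterrows():
            fh.write(f"{r['chrom']}\t{r['marker']}\t0\t{int(r['pos'])}\n")
    alleles = mp[["a1", "a2"]].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, aid in enumerate(panel.ids):
            fields = [aid, aid, "0", "0", "0", "-9"]
            row = panel.dosages[i]
            for j, d in enumerate(row):
                a1, a2 = alleles[j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a1, a1]
                elif d == 1:
                    fields += [a1, a2]
                else:
                    fields += [a2, a2]
            fh.write(" ".join(fields) + "\n")


def read_plink(prefix, label: str = "panel") -> GenotypePanel:
    prefix = Path(prefix)
    mp = pd.read_csv(prefix.with_suffix(".map"), sep="\t", header=None,
                     names=["chrom", "marker", "cm", "pos"],
                     dtype={"chrom": str, "marker": str})
    ids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1])
            geno = parts[6:]
            dos = np.empty(len(mp))
            for j in range(len(mp)):
                a, b = geno[2 * j], geno[2 * j + 1]
                if a == "0" or b == "0":
                    dos[j] = np.nan
                else:
                    dos[j] = (a != "A") + (b != "A")
            rows.append(dos)
    markers = pd.DataFrame({"marker": mp["marker"], "chrom": mp["chrom"],
                            "pos": mp["pos"], "a1": "A", "a2": "B"})
    return GenotypePanel(ids=ids, dosages=np.array(rows), markers=markers,
                         label=label)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal VCF with GT and DS per sample (unphased hard calls)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(set(panel.markers["chrom"]), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.ids) + "\n")
        for j, r in panel.markers.iterrows():
            cells = []
            for i in range(panel.n_individuals):
                d = panel.dosages[i, j]
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(round(d))]
                    cells.append(f"{gt}:{d:g}")
            fh.write(f"{r['chrom']}\t{int(r['pos'])}\t{r['marker']}\tA\tC\t.\t.\t.\t"
                     "GT:DS\t" + "\t".join(cells) + "\n")


def read_vcf(path, label: str = "panel") -> GenotypePanel:
    """Read GT (and DS when present) into a dosage panel via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, markers = [], []
    for var in vcf:
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).ravel()
            dos = np.where(np.isfinite(dos), dos, np.nan)
        else:
            gts = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            dos = np.where(gts == 3, 2.0, gts.astype(float))
            dos = np.where(gts == 2, np.nan, dos)
        rows.append(dos)
        markers.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM),
                        int(var.POS), var.REF, var.ALT[0] if var.ALT else "."))
    mk = pd.DataFrame(markers, columns=["marker", "chrom", "pos", "a1", "a2"])
    return GenotypePanel(ids=ids, dosages=np.array(rows).T, markers=mk,
                         label=label)


# ---------------------------------------------------------------------------
# QTL tables


def write_qtl_regions(table: pd.DataFrame, path) -> None:
    table[["chrom", "start", "end", "trait_category", "source"]].to_csv(
        path, sep="\t", index=False)


def read_qtl_regions(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"chrom", "start", "end"}
    if not need <= set(t.columns):
        raise DataError(f"QTL table needs columns {sorted(need)}")
    return t


def qtl_regions_from_gff(path, feature_type: str = "QTL") -> pd.DataFrame:
    """Convert a GFF-like file (9 tab-separated columns) to the region table.

    The trait category is taken from a ``trait=`` or ``Name=`` key in
    the attribute column when present.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or (feature_type and parts[2] != feature_type):
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";")
                         if "=" in kv)
            trait = attrs.get("trait", attrs.get("Name", ""))
            rows.append((parts[0], int(parts[3]), int(parts[4]), trait,
                         parts[1]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "trait_category", "source"])


# ---------------------------------------------------------------------------
# relationship matrices


def write_matrix_text(matrix: RelationshipMatrix, path) -> None:
    """Id-indexed lower-triangle text format (row id, col id, value)."""
    with open(path, "w") as fh:
        fh.write(f"#kind={matrix.kind}\n")
        for i, a in enumerate(matrix.ids):
            for j in range(i + 1):
                fh.write(f"{a}\t{matrix.ids[j]}\t{float(matrix.values[i, j])!r}\n")


def read_matrix_text(path) -> RelationshipMatrix:
    kind = "A"
    ids: list[str] = []
    pos: dict[str, int] = {}
    triples = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if line.startswith("#kind="):
                    kind = line.strip().split("=", 1)[1]
                continue
            a, b, v = line.rstrip("\n").split("\t")
            for x in (a, b):
                if x not in pos:
                    pos[x] = len(ids)
                    ids.append(x)
            triples.append((pos[a], pos[b], float(v)))
    n = len(ids)
    M = np.zeros((n, n))
    for i, j, v in triples:
        M[i, j] = v
        M[j, i] = v
    return RelationshipMatrix(ids=ids, values=M, kind=kind)


def write_matrix_npz(matrix: RelationshipMatrix, path) -> None:
    """Binary container with an id header; round-trips bit-exactly."""
    np.savez_compressed(path, values=matrix.values,
                        ids=np.array(matrix.ids, dtype=object),
                        kind=np.array(matrix.kind))


def read_matrix_npz(path) -> RelationshipMatrix:
    with np.load(path, allow_pickle=True) as z:
        return RelationshipMatrix(ids=[str(a) for a in z["ids"]],
                                  values=z["values"], kind=str(z["kind"]))


# ---------------------------------------------------------------------------
# results


def write_vc_report(vc, path_prefix) -> None:
    """Variance components + convergence trace as JSON and plain text."""
    prefix = Path(path_prefix)
    payload = {"sigma2": vc.sigma2, "sigma2_e": vc.sigma2_e,
               "loglik": vc.loglik, "iterations": vc.iterations,
               "converged": vc.converged, "trace": vc.trace}
    prefix.with_suffix(".json").write_text(json.dumps(payload, indent=2))
    lines = [f"{k}: {v:.6g}" for k, v in vc.sigma2.items()]
    lines.append(f"residual: {vc.sigma2_e:.6g}")
    lines.append(f"logL: {vc.loglik:.6f} after {vc.iterations} iterations "
                 f"(converged={vc.converged})")
    prefix.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def write_solutions(solution, path) -> None:
    """CSV (id, term, prediction[, pev]) for every random term."""
    rows = []
    for term, u in solution.u.items():
        pev = solution.pev.get(term) if solution.pev else None
        for k, aid in enumerate(solution.level_ids[term]):
            rows.append({"id": aid, "term": term, "prediction": u[k],
                         "pev": pev[k] if pev is not None else np.nan})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
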