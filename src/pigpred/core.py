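"""Core data containers shared across the pipeline.

The pipeline moves three kinds of objects around: genotype panels
(individuals x markers dosage matrices with a marker map), pedigrees
(animal/sire/dam records with dates and population labels), and
relationship matrices keyed by animal ids.  Everything downstream --
quality control, relationship-matrix construction, mixed-model fitting
and scenario evaluation -- consumes these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Pig autosomes are numbered 1..18; anything else is treated as non-autosomal.
AUTOSOMES = frozenset(str(c) for c in range(1, 19))

MISSING_PARENT = "0"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class NumericalError(RuntimeError):
    """A numerical procedure failed (singular system, non-convergence)."""


@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x markers) plus marker map.

    Parameters
    ----------
    ids
        Individual identifiers, one per dosage row.
    dosages
        Array of shape ``(n_individuals, n_markers)`` holding allele
        dosages in ``{0, 1, 2}``; ``NaN`` marks a missing genotype.
    markers
        Marker map with columns ``marker, chrom, pos, a1, a2``
        (1-based, inclusive bp positions; chrom stored as string).
    label
        Panel provenance tag, e.g. ``"chip"``, ``"seq"`` or ``"seq_pruned"``.
    """

    ids: list[str]
    dosages: np.ndarray
    markers: pd.DataFrame
    label: str = "panel"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.markers)):
            raise DataError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} ids x {len(self.markers)} markers"
            )
        self.markers = self.markers.reset_index(drop=True)
        self.markers["chrom"] = self.markers["chrom"].astype(str)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["marker"].tolist()

    def allele_freq(self) -> np.ndarray:
        """Observed alternate-allele frequency per marker (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by the marker mean."""
        m = self.dosages.copy()
        if np.isnan(m).any():
            col_mean = np.nanmean(m, axis=0)
            idx = np.where(np.isnan(m))
            m[idx] = col_mean[idx[1]]
        return m

    def subset_markers(self, mask_or_names, label: str | None = None) -> "GenotypePanel":
        if isinstance(mask_or_names, (list, set, frozenset, pd.Index)):
            names = set(mask_or_names)
            mask = self.markers["marker"].isin(names).to_numpy()
        else:
            mask = np.asarray(mask_or_names)
            if mask.dtype != bool:
                full = np.zeros(self.n_markers, dtype=bool)
                full[mask] = True
                mask = full
        return GenotypePanel(
            ids=list(self.ids),
            dosages=self.dosages[:, mask],
            markers=self.markers.loc[mask].reset_index(drop=True),
            label=label or self.label,
        )

    def subset_ids(self, ids: list[str]) -> "GenotypePanel":
        index = {a: i for i, a in enumerate(self.ids)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise DataError(f"ids absent from panel: {missing[:5]}")
        rows = [index[a] for a in ids]
        return GenotypePanel(
            ids=list(ids),
            dosages=self.dosages[rows],
            markers=self.markers.copy(),
            label=self.label,
        )


@dataclass
class Pedigree:
    """Pedigree table with one row per animal.

    Columns: ``id, sire, dam, sex, birth_date, population, herd``.
    Unknown parents are coded ``"0"``; sex follows the PLINK convention
    (1 = male, 2 = female).  Rows are kept in topological order
    (parents before offspring), sorting on construction if needed.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("id", "sire", "dam"):
            t[col] = t[col].astype(str)
        if t["id"].duplicated().any():
            dup = t.loc[t["id"].duplicated(), "id"].iloc[0]
            raise DataError(f"duplicate animal id {dup!r} in pedigree")
        self.table = _topological_sort(t)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam row indices in topological order; -1 for unknown."""
        pos = {a: i for i, a in enumerate(self.table["id"])}
        sire = np.array([pos.get(s, -1) for s in self.table["sire"]], dtype=np.int64)
        dam = np.array([pos.get(d, -1) for d in self.table["dam"]], dtype=np.int64)
        return sire, dam

    def birth_dates(self) -> pd.Series:
        return pd.to_datetime(self.table.set_index("id")["birth_date"])


def _topological_sort(t: pd.DataFrame) -> pd.DataFrame:
    """Order pedigree rows parents-before-offspring, detecting cycles."""
    known = set(t["id"])
    children: dict[str, list[str]] = {}
    indeg = {a: 0 for a in t["id"]}
    for _, row in t.iterrows():
        for par in (row["sire"], row["dam"]):
            if par != MISSING_PARENT and par in known:
                children.setdefault(par, []).append(row["id"])
                indeg[row["id"]] += 1
            elif par != MISSING_PARENT and par not in known:
                raise DataError(f"parent {par!r} of {row['id']!r} missing from pedigree")
    order: list[str] = []
    frontier = [a for a in t["id"] if indeg[a] == 0]
    while frontier:
        nxt: list[str] = []
        for a in frontier:
            order.append(a)
            for c in children.get(a, []):
                indeg[c] -= 1
                if indeg[c] == 0:
                    nxt.append(c)
        frontier = nxt
    if len(order) != len(t):
        cyc = sorted(set(t["id"]) - set(order))
        raise DataError(f"pedigree cycle: animal is its own ancestor near {cyc[:3]}")
    return t.set_index("id").loc[order].reset_index()


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix keyed by animal ids.

    ``kind`` is a provenance tag: ``A`` (pedigree), ``A22`` (genotyped
    block of A), ``G`` (VanRaden genomic), ``Ga`` (rescaled G), ``Gw``
    (blended), or ``H`` (single-step, assembled for inspection only).
    ``meta`` carries construction details such as the VanRaden scaling
    constant ``scale = 2 * sum p(1-p)``.
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "A"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DataError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataError("relationship matrix is not symmetric")
        # enforce exact symmetry for downstream factorizations
        self.values = 0.5 * (self.values + self.values.T)

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        rows = np.array([pos[a] for a in ids])
        return RelationshipMatrix(
            ids=list(ids),
            values=self.values[np.ix_(rows, rows)],
            kind=self.kind,
            meta=dict(self.meta),
        )

    def reorder_like(self, ids: list[str]) -> "RelationshipMatrix":
        return self.subset(ids)


def pearson(x, y) -> float:
    """Pearson correlation as a plain float (NaN-free inputs assumed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
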