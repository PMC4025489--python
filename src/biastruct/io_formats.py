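"""Readers and writers for genotype matrices, labels, ancestry output and configs.

Genotypes travel as a :class:`GenotypeTable`: an N x M matrix of
alternate-allele counts (0/1/2, missing = 9) with individual and locus ids.
The on-disk dialects are EIGENSTRAT (.geno/.ind/.snp companions, one row per
locus, one digit per individual) and a plain TSV (individuals x loci with a
header row).  Readers and writers are exact inverses on valid input; missing
genotypes are never imputed at the I/O level.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

MISSING = 9
_VALID_CODES = frozenset((0, 1, 2, MISSING))


@dataclasses.dataclass
class GenotypeTable:
    """N individuals x M loci matrix of alternate-allele counts.

    Entries are 0, 1 or 2 copies of the alternate allele, or 9 for missing.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        n, m = self.matrix.shape
        if n != len(self.individual_ids):
            raise ValueError(
                f"matrix has {n} rows but {len(self.individual_ids)} individual ids"
            )
        if m != len(self.locus_ids):
            raise ValueError(
                f"matrix has {m} columns but {len(self.locus_ids)} locus ids"
            )
        bad = set(np.unique(self.matrix)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}; allowed 0/1/2/9")

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_loci(self) -> int:
        return self.matrix.shape[1]

    def take(self, indices: np.ndarray, ids: list[str] | None = None) -> "GenotypeTable":
        """Row-subset (with possible repetition) keeping locus metadata."""
        indices = np.asarray(indices)
        if ids is None:
            ids = [self.individual_ids[i] for i in indices]
        return GenotypeTable(ids, list(self.locus_ids), self.matrix[indices])


@dataclasses.dataclass
class LabelTable:
    """Group label u per individual (1 = unmixed pop 1, 2 = unmixed pop 2,
    3 = admixed) plus, when known, the true ancestry proportion theta in [0,1]
    (fraction of the genome from population 2)."""

    individual_ids: list[str]
    group: np.ndarray
    true_theta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=np.int64)
        if len(self.group) != len(self.individual_ids):
            raise ValueError("one group label required per individual")
        if not np.isin(self.group, (1, 2, 3)).all():
            raise ValueError("group labels must be in {1, 2, 3}")
        if self.true_theta is not None:
            self.true_theta = np.asarray(self.true_theta, dtype=float)
            if len(self.true_theta) != len(self.individual_ids):
                raise ValueError("one theta required per individual")
            if ((self.true_theta < 0) | (self.true_theta > 1)).any():
                raise ValueError("true_theta must lie in [0, 1]")

    def take(self, indices: np.ndarray, ids: list[str] | None = None) -> "LabelTable":
        indices = np.asarray(indices)
        if ids is None:
            ids = [self.individual_ids[i] for i in indices]
        theta = None if self.true_theta is None else self.true_theta[indices]
        return LabelTable(ids, self.group[indices], theta)


# ---------------------------------------------------------------------------
# genotype I/O


def read_genotypes(path: str | Path, format: str = "eigenstrat") -> GenotypeTable:
    """Read a genotype matrix.

    ``eigenstrat``: `path` is the prefix of a .geno/.ind/.snp trio. The .geno
    file holds one row per locus with one digit per individual; .ind and .snp
    are authoritative for individual and locus ordering.  ``tsv``: `path` is a
    tab-separated individuals x loci table with a header row of locus ids and
    an index column of individual ids.
    """
    if format == "eigenstrat":
        return _read_eigenstrat(Path(path))
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return GenotypeTable(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=np.int8),
        )
    raise ValueError(f"unknown format {format!r}")


def _read_eigenstrat(prefix: Path) -> GenotypeTable:
    geno = Path(str(prefix) + ".geno")
    lines = [ln for ln in geno.read_text().splitlines() if ln]
    if not lines:
        raise ValueError(f"{geno}: no loci")
    ind_ids = [ln.split()[0] for ln in Path(str(prefix) + ".ind").read_text().splitlines() if ln.strip()]
    snp_ids = [ln.split()[0] for ln in Path(str(prefix) + ".snp").read_text().splitlines() if ln.strip()]
    if len(snp_ids) != len(lines):
        raise ValueError(
            f"{geno}: {len(lines)} rows but .snp lists {len(snp_ids)} loci"
        )
    rows = []
    for ln in lines:
        if not ln.isdigit():
            raise ValueError(f"{geno}: non-digit characters in row {ln!r}")
        if len(ln) != len(ind_ids):
            raise ValueError(
                f"{geno}: row width {len(ln)} but .ind lists {len(ind_ids)} individuals"
            )
        row = np.frombuffer(ln.encode(), dtype=np.uint8) - ord("0")
        bad = set(np.unique(row)) - _VALID_CODES
        if bad:
            raise ValueError(f"{geno}: unknown genotype digit(s) {sorted(bad)}")
        rows.append(row)
    matrix = np.array(rows, dtype=np.int8).T  # loci-major on disk -> N x M
    return GenotypeTable(ind_ids, snp_ids, matrix)


def write_genotypes(table: GenotypeTable, path: str | Path, format: str = "eigenstrat") -> None:
    """Write a genotype matrix; `read_genotypes` parses the result back exactly."""
    path = Path(path)
    if format == "eigenstrat":
        digits = table.matrix.T.astype(np.uint8) + ord("0")
        lines = [bytes(row).decode() for row in digits]
        Path(str(path) + ".geno").write_text("\n".join(lines) + "\n")
        Path(str(path) + ".ind").write_text(
            "".join(f"{i}\tU\tPop\n" for i in table.individual_ids)
        )
        Path(str(path) + ".snp").write_text(
            "".join(f"{s}\t1\t0.0\t{k + 1}\n" for k, s in enumerate(table.locus_ids))
        )
    elif format == "tsv":
        df = pd.DataFrame(table.matrix, index=table.individual_ids, columns=table.locus_ids)
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_labels(labels: LabelTable, path: str | Path) -> None:
    df = pd.DataFrame({"individual": labels.individual_ids, "group": labels.group})
    if labels.true_theta is not None:
        df["true_theta"] = labels.true_theta
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> LabelTable:
    df = pd.read_csv(path, sep="\t")
    theta = df["true_theta"].to_numpy() if "true_theta" in df.columns else None
    return LabelTable([str(i) for i in df["individual"]], df["group"].to_numpy(), theta)


def write_qmatrix(q: np.ndarray, path: str | Path) -> None:
    """Write an ancestry matrix Q, one row per individual, 6-decimal reals.

    Mirrors the .Q convention of admixture-style output.
    """
    q = np.asarray(q, dtype=float)
    if not np.isfinite(q).all():
        raise ValueError("Q contains non-finite entries")
    with open(path, "w") as fh:
        for row in q:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_qmatrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, ndmin=2)


# ---------------------------------------------------------------------------
# experiment configuration


_CONFIG_DEFAULTS: dict[str, object] = {
    "n_loci": 10_000,
    "fst": 0.1,
    "n_founders": 50,
    "n_admixed": 800,
    "n_generations": 7,  # one admixture generation + six of random mating
    "unmixed_pool": 100,
    "x": [10, 30, 50, 100],
    "y": [10, 30, 100, 200, 400, 700],
    "z": None,  # None -> same values as x
    "symmetric_only": True,
    "n_replicates": 5,
    "engine": "em",
    "correction": "none",
    "seed": 0,
    "demography": None,  # {"alpha": float, "n0": int}
}

_ALLOWED_ENGINES = {"em", "eigen"}
_ALLOWED_CORRECTIONS = {"none", "resample", "weights"}


@dataclasses.dataclass
class ExperimentConfig:
    """Validated experiment settings with defaults filled in.

    `cells` enumerates the (x, y, z) sampling specifications of the grid: the
    counts of unmixed pop-1, admixed and unmixed pop-2 individuals drawn into
    each biased dataset.
    """

    n_loci: int
    fst: float
    n_founders: int
    n_admixed: int
    n_generations: int
    unmixed_pool: int
    cells: list[tuple[int, int, int]]
    symmetric_only: bool
    n_replicates: int
    engine: str
    correction: str
    seed: int
    demography: dict | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")
        if not 0 < self.fst < 0.5:
            raise ValueError("fst must lie in (0, 0.5)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.engine not in _ALLOWED_ENGINES:
            raise ValueError(f"engine must be one of {sorted(_ALLOWED_ENGINES)}")
        if self.correction not in _ALLOWED_CORRECTIONS:
            raise ValueError(f"correction must be one of {sorted(_ALLOWED_CORRECTIONS)}")
        for cell in self.cells:
            if min(cell) < 1:
                raise ValueError(f"cell {cell}: all counts must be >= 1")


def build_config(raw: dict) -> ExperimentConfig:
    """Validate a raw key-value mapping and fill defaults."""
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_CONFIG_DEFAULTS, **raw}
    xs = list(merged.pop("x"))
    ys = list(merged.pop("y"))
    zs = merged.pop("z")
    zs = xs if zs is None else list(zs)
    symmetric = bool(merged["symmetric_only"])
    cells = [
        (x, y, z)
        for x in xs
        for y in ys
        for z in zs
        if not symmetric or x == z
    ]
    return ExperimentConfig(cells=cells, **merged)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML experiment config, applying defaults and validation."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a key-value mapping")
    return build_config(raw)
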