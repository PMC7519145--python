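"""Trial-network data model: phenotype records, SNP genotypes with QC,
connectivity diagnostics and cross-validation fold assignment.

A multi-environment trial network holds one un-replicated trial per
year–location; each trial tests a subset of the cultivar roster, and trials
are connected through shared cultivars (a common check plus partial overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream

__all__ = [
    "TrialDataset",
    "GenotypeMatrix",
    "FoldAssignment",
    "qc_filter_snps",
    "impute_and_standardize",
    "connectivity_index",
    "assign_folds",
    "read_phenotypes_csv",
    "read_genotypes_csv",
    "read_genotypes_vcf",
]


@dataclass
class TrialDataset:
    """Long-format yield records keyed by (year, location, cultivar).

    ``records`` columns: year, location, cultivar, yield (tons/ha). At most
    one record per key (un-replicated trials); every trial has ≥ 1 record.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"year", "location", "cultivar", "yield"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        df = self.records.reset_index(drop=True)
        if df.duplicated(["year", "location", "cultivar"]).any():
            raise ValueError("duplicate (year, location, cultivar) record; trials are un-replicated")
        if len(df) == 0:
            raise ValueError("empty phenotype table")
        self.records = df

    @property
    def trials(self) -> pd.DataFrame:
        """Distinct (year, location) pairs."""
        return self.records[["year", "location"]].drop_duplicates().reset_index(drop=True)

    @property
    def trial_ids(self) -> list[tuple]:
        return list(map(tuple, self.trials.to_numpy()))

    @property
    def cultivars(self) -> list:
        return sorted(self.records["cultivar"].unique().tolist())

    @property
    def years(self) -> list:
        return sorted(self.records["year"].unique().tolist())

    @property
    def locations(self) -> list:
        return sorted(self.records["location"].unique().tolist())

    def trial_rosters(self) -> dict[tuple, frozenset]:
        """Cultivar set tested in each trial."""
        out = {}
        for (y, l), g in self.records.groupby(["year", "location"], sort=False):
            out[(y, l)] = frozenset(g["cultivar"])
        return out

    def check_genotype_links(self, gm: "GenotypeMatrix") -> None:
        unknown = set(self.records["cultivar"]) - set(gm.cultivars)
        if unknown:
            raise ValueError(f"cultivars without genotypes: {sorted(unknown)[:5]}...")

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def read_phenotypes_csv(path) -> TrialDataset:
    return TrialDataset(pd.read_csv(path))


@dataclass
class GenotypeMatrix:
    """Cultivar × SNP dosage matrix (0/1/2, NaN = missing) with QC metadata.

    ``X`` (the centered/scaled matrix) is populated by
    :func:`impute_and_standardize`; ``qc_report`` by :func:`qc_filter_snps`.
    """

    dosages: pd.DataFrame  # rows = cultivars, columns = SNP ids
    X: pd.DataFrame | None = None
    qc_report: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def cultivars(self) -> list:
        return self.dosages.index.tolist()

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequency(self) -> pd.Series:
        """ALT-allele frequency per SNP over non-missing calls."""
        return self.dosages.mean(skipna=True) / 2.0

    def call_rate(self) -> pd.Series:
        return self.dosages.notna().mean()

    def het_fraction(self) -> pd.Series:
        het = (self.dosages == 1).sum()
        n = self.dosages.notna().sum()
        return het / n.replace(0, np.nan)


def qc_filter_snps(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    cr_min: float = 0.8,
    het_max: float = 0.10,
) -> GenotypeMatrix:
    """Retain SNPs with MAF > maf_min, call rate > cr_min and heterozygous
    fraction < het_max; attach a per-SNP pass/fail report.

    Raises ``ValueError`` naming the binding filter if no SNP survives.
    """
    freq = gm.allele_frequency()
    maf = np.minimum(freq, 1.0 - freq)
    cr = gm.call_rate()
    het = gm.het_fraction().fillna(1.0)
    report = pd.DataFrame(
        {
            "maf": maf,
            "call_rate": cr,
            "het_fraction": het,
            "pass_maf": maf > maf_min,
            "pass_call_rate": cr > cr_min,
            "pass_het": het < het_max,
        }
    )
    report["pass"] = report[["pass_maf", "pass_call_rate", "pass_het"]].all(axis=1)
    kept = report.index[report["pass"]]
    if len(kept) == 0:
        fails = {
            "maf": int((~report["pass_maf"]).sum()),
            "call_rate": int((~report["pass_call_rate"]).sum()),
            "het_fraction": int((~report["pass_het"]).sum()),
        }
        binding = max(fails, key=fails.get)
        raise ValueError(
            f"no SNP passes QC; binding filter: {binding} ({fails[binding]}/{gm.n_snps} failures)"
        )
    return GenotypeMatrix(gm.dosages[kept], qc_report=report)


def impute_and_standardize(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Impute missing dosages to the mean (2 × allele frequency), then center
    and scale each SNP column to unit variance (sample sd, ddof=1)."""
    freq = gm.allele_frequency()
    filled = gm.dosages.astype(float).fillna(2.0 * freq)
    sd = filled.std(ddof=1)
    if (sd == 0).any() or sd.isna().any():
        dead = sd.index[(sd == 0) | sd.isna()].tolist()
        raise ValueError(f"zero-variance SNP columns after imputation: {dead[:5]}")
    X = (filled - filled.mean()) / sd
    return GenotypeMatrix(gm.dosages, X=X, qc_report=gm.qc_report)


def connectivity_index(d: TrialDataset, r: int = 1) -> tuple[pd.Series, float]:
    """Number of other trials sharing ≥ r cultivars with each trial.

    Returns (per-trial counts indexed by (year, location), network mean T̄(r)).
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    rosters = d.trial_rosters()
    keys = list(rosters)
    sets = [rosters[k] for k in keys]
    n = len(keys)
    counts = np.zeros(n, dtype=int)
    for a in range(n):
        for b in range(a + 1, n):
            if len(sets[a] & sets[b]) >= r:
                counts[a] += 1
                counts[b] += 1
    ser = pd.Series(counts, index=pd.MultiIndex.from_tuples(keys, names=["year", "location"]))
    return ser, float(ser.mean())


@dataclass
class FoldAssignment:
    """Balanced random partition of units (trials or cultivars) into k folds."""

    scheme: str  # "by-trial" | "by-cultivar"
    k: int
    assignment: dict  # unit -> fold index (0..k-1)
    seed: int

    def __post_init__(self) -> None:
        sizes = self.fold_sizes()
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes differ by more than 1")

    def fold_sizes(self) -> list[int]:
        return [sum(1 for f in self.assignment.values() if f == i) for i in range(self.k)]

    def units_in_fold(self, fold: int) -> list:
        return [u for u, f in self.assignment.items() if f == fold]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"unit": [str(u) for u in self.assignment], "fold": list(self.assignment.values())}
        ).to_csv(path, index=False)


def assign_folds(
    d: TrialDataset, scheme: str = "by-trial", k: int = 10, seed: int = 0
) -> FoldAssignment:
    """Randomly assign trials (or cultivars) to k balanced folds."""
    if scheme == "by-trial":
        units = d.trial_ids
    elif scheme == "by-cultivar":
        units = d.cultivars
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(units):
        raise ValueError(f"k={k} exceeds number of units ({len(units)})")
    rng = stream(seed, f"folds:{scheme}:{k}")
    order = rng.permutation(len(units))
    assignment = {units[j]: int(i % k) for i, j in enumerate(order)}
    return FoldAssignment(scheme=scheme, k=k, assignment=assignment, seed=seed)


def read_genotypes_csv(path) -> GenotypeMatrix:
    """Read a plain cultivar × SNP dosage matrix (first column = cultivar id)."""
    df = pd.read_csv(path, index_col=0)
    return GenotypeMatrix(df)


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF; dosage = count of ALT alleles.

    Multi-allelic sites are rejected. Sample order follows the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, cols = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic site at {variant.CHROM}:{variant.POS}; split or filter first"
            )
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        ids.append(vid)
        cols.append(dos)
    if not ids:
        raise ValueError("no variants in VCF")
    mat = pd.DataFrame(np.column_stack(cols), index=samples, columns=ids)
    return GenotypeMatrix(mat)
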