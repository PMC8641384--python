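"""Containers and file I/O for genotype panels, expression panels and SNP-weight tables.

Conventions
-----------
* In-memory matrices are 0-based numpy arrays; files carry 1-based, closed
  coordinates (the VCF convention).
* Genotypes are alt-allele dosages in [0, 2]; ``NaN`` marks a missing call.
* The cis window around a gene is the closed interval
  ``[start - window, end + window]``.
* Parsers reject malformed input with :class:`ParseError` rather than coercing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("twasbench")

CIS_WINDOW = 1_000_000  # bp on either side of the gene body
MAF_MIN = 0.01

SNP_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]
GENE_COLUMNS = ["id", "chrom", "start", "end"]


class PanelError(ValueError):
    """Inconsistent panel contents."""


class EmptyPanelError(PanelError):
    """An operation left a panel with no SNPs (gene is skipped, not crashed)."""


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Samples x SNPs dosage matrix plus SNP and sample metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` float array of alt-allele dosages in [0, 2];
        NaN marks missing calls.
    snps
        DataFrame with columns ``id, chrom, pos, ref, alt`` (``pos`` 1-based).
    samples
        DataFrame with columns ``id, population``.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise PanelError("dosage matrix must be 2-D (samples x SNPs)")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise PanelError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.snps["id"].duplicated().any():
            dup = self.snps.loc[self.snps["id"].duplicated(), "id"].iloc[0]
            raise ParseError(f"duplicated SNP id {dup!r}")
        if self.samples["id"].duplicated().any():
            dup = self.samples.loc[self.samples["id"].duplicated(), "id"].iloc[0]
            raise ParseError(f"duplicated sample id {dup!r}")
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise PanelError(f"positions not strictly increasing on {chrom}")

    # -- basic views --------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["id"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["id"].to_numpy()

    def subset_snps(self, index) -> "GenotypePanel":
        """Return a panel restricted to the SNPs selected by ``index``
        (boolean mask or integer positions); SNP order is preserved."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypePanel(
            self.dosages[:, index], self.snps.iloc[index], self.samples
        )

    def subset_samples(self, index) -> "GenotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypePanel(
            self.dosages[index, :], self.snps, self.samples.iloc[index]
        )

    def population(self, label: str) -> "GenotypePanel":
        """Samples of one population, with that population's MAF/missing QC applied."""
        mask = (self.samples["population"] == label).to_numpy()
        if not mask.any():
            raise PanelError(f"no samples with population label {label!r}")
        return qc_filter(self.subset_samples(mask))

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency, min(p, 1-p) with p = mean dosage / 2."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


@dataclass
class ExpressionPanel:
    """Samples x genes expression matrix plus gene coordinates."""

    values: np.ndarray
    genes: pd.DataFrame  # columns: id, chrom, start, end
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = self.genes.reset_index(drop=True)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.values.shape != (len(self.sample_ids), len(self.genes)):
            raise PanelError("expression shape does not match samples x genes")
        if self.genes["id"].duplicated().any():
            raise ParseError("duplicated gene id in expression panel")
        if pd.Series(self.sample_ids).duplicated().any():
            raise ParseError("duplicated sample id in expression panel")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.genes["id"].to_numpy()

    def gene_record(self, gene: str) -> pd.Series:
        hit = self.genes.index[self.genes["id"] == gene]
        if len(hit) == 0:
            raise KeyError(f"unknown gene {gene!r}")
        return self.genes.loc[hit[0]]

    def expression(self, gene: str) -> np.ndarray:
        hit = np.flatnonzero(self.gene_ids == gene)
        if len(hit) == 0:
            raise KeyError(f"unknown gene {gene!r}")
        return self.values[:, hit[0]]

    def subset_samples(self, index) -> "ExpressionPanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ExpressionPanel(self.values[index, :], self.genes, self.sample_ids[index])


@dataclass
class GeneModel:
    """A trained per-gene predictor.

    Linear methods are represented by SNP weights; standardization statistics
    from the training panel are kept so that the model can be applied both to
    standardized matrices and to raw dosages.  Random-Forest models carry an
    opaque fitted-ensemble handle and are flagged not weight-representable.
    """

    gene: str
    method: str
    snp_ids: np.ndarray
    alt: np.ndarray
    weights_std: np.ndarray | None  # on the standardized-genotype scale
    center: np.ndarray
    scale: np.ndarray
    y_mean: float
    tuning: dict = field(default_factory=dict)
    estimator: object | None = None  # opaque handle (Random Forests)
    weight_representable: bool = True

    @property
    def weights_dosage(self) -> np.ndarray:
        """Weights back-transformed to the alt-allele dosage scale."""
        if self.weights_std is None:
            raise PanelError(f"{self.method} model for {self.gene} has no weight table")
        return self.weights_std / self.scale

    @property
    def intercept_dosage(self) -> float:
        if self.weights_std is None:
            raise PanelError(f"{self.method} model for {self.gene} has no weight table")
        return float(self.y_mean - np.sum(self.weights_std * self.center / self.scale))

    def predict(self, dosages: np.ndarray) -> np.ndarray:
        """Predict expression from a raw dosage matrix whose columns match
        ``snp_ids`` in order."""
        X = (np.asarray(dosages, dtype=float) - self.center) / self.scale
        if self.estimator is not None:
            return np.asarray(self.estimator.predict(X), dtype=float)
        return self.y_mean + X @ self.weights_std


# ---------------------------------------------------------------------------
# cis-window extraction and QC
# ---------------------------------------------------------------------------

def extract_cis(panel: GenotypePanel, gene, window: int = CIS_WINDOW) -> GenotypePanel:
    """SNPs within ``window`` bp of the gene body (closed interval, 1-based).

    ``gene`` is any mapping with ``chrom``, ``start`` and ``end`` entries.
    Raises :class:`EmptyPanelError` when no SNP falls in the window; callers
    skip the gene rather than crash.
    """
    chrom = gene["chrom"]
    lo = int(gene["start"]) - window
    hi = int(gene["end"]) + window
    pos = panel.snps["pos"].to_numpy()
    mask = (panel.snps["chrom"].to_numpy() == chrom) & (pos >= lo) & (pos <= hi)
    if not mask.any():
        raise EmptyPanelError(
            f"no SNPs within {window} bp of {gene.get('id', chrom)} [{lo}, {hi}]"
        )
    return panel.subset_snps(mask)


def qc_filter(panel: GenotypePanel, maf_min: float = MAF_MIN) -> GenotypePanel:
    """Drop SNPs with MAF < ``maf_min`` (strict) or any missing dosage."""
    missing = np.isnan(panel.dosages).any(axis=0)
    maf = panel.maf()
    keep = ~missing & (maf >= maf_min) & ~np.isnan(maf)
    n_dropped = panel.n_snps - int(keep.sum())
    if n_dropped:
        logger.debug("qc_filter: dropped %d/%d SNPs", n_dropped, panel.n_snps)
    if not keep.any():
        raise EmptyPanelError("all SNPs removed by QC")
    return panel.subset_snps(keep)


def align_samples(panel: GenotypePanel, expr: ExpressionPanel):
    """Restrict both panels to their shared samples, in the genotype panel's order."""
    common = pd.Index(panel.sample_ids).intersection(expr.sample_ids)
    if len(common) == 0:
        raise PanelError("genotype and expression panels share no samples")
    gidx = pd.Index(panel.sample_ids).get_indexer(common)
    eidx = pd.Index(expr.sample_ids).get_indexer(common)
    return panel.subset_samples(gidx), expr.subset_samples(eidx)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_dosage_vcf(panel: GenotypePanel, path) -> None:
    """Write a VCF with a single DS (dosage) FORMAT field, 1-based positions."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        for chrom in pd.unique(panel.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(str(s) for s in panel.sample_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        D = panel.dosages
        for j, rec in panel.snps.iterrows():
            vals = [
                "." if np.isnan(D[i, j]) else format(D[i, j], ".6f")
                for i in range(panel.n_samples)
            ]
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t{rec['id']}\t{rec['ref']}\t"
                f"{rec['alt']}\t.\t.\t.\tDS\t" + "\t".join(vals) + "\n"
            )


def read_dosage_vcf(path, populations=None) -> GenotypePanel:
    """Read a DS-field dosage VCF into a :class:`GenotypePanel`.

    ``populations`` optionally maps sample id -> population label (defaults
    to ``"pop0"`` for every sample; VCF itself carries no population field).
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    if len(sample_ids) != len(set(sample_ids)):
        raise ParseError(f"duplicated sample id in VCF header of {path}")
    rows, recs = [], []
    for v in vcf:
        ds = v.format("DS")
        if ds is None:
            raise ParseError(f"record {v.ID or v.POS} in {path} lacks a DS field")
        ds = np.asarray(ds, dtype=float).reshape(-1)
        ds[(ds < 0) | (ds > 2)] = np.nan  # cyvcf2 encodes '.' as a sentinel
        rows.append(ds)
        recs.append(
            dict(id=v.ID, chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0])
        )
    vcf.close()
    if not recs:
        raise ParseError(f"VCF {path} contains no variant records")
    populations = populations or {}
    samples = pd.DataFrame(
        {"id": sample_ids, "population": [populations.get(s, "pop0") for s in sample_ids]}
    )
    return GenotypePanel(np.column_stack(rows), pd.DataFrame(recs), samples)


def write_dosage_tsv(panel: GenotypePanel, path, snp_path=None, sample_path=None) -> None:
    """Plain TSV dosage table (rows = samples, columns = SNP ids), with optional
    side tables for SNP metadata and sample population labels."""
    df = pd.DataFrame(panel.dosages, index=panel.sample_ids, columns=panel.snp_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.6f")
    if snp_path is not None:
        panel.snps.to_csv(snp_path, sep="\t", index=False)
    if sample_path is not None:
        panel.samples.to_csv(sample_path, sep="\t", index=False)


def _check_unique_header(path) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = pd.Series(header)[pd.Series(header).duplicated()]
    if len(dup):
        raise ParseError(f"duplicated column id {dup.iloc[0]!r} in {path}")


def read_dosage_tsv(path, snp_path=None, sample_path=None) -> GenotypePanel:
    _check_unique_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ParseError(f"duplicated sample id in {path}")
    if snp_path is not None:
        snps = pd.read_csv(snp_path, sep="\t")
        missing_cols = set(SNP_COLUMNS) - set(snps.columns)
        if missing_cols:
            raise ParseError(f"SNP table {snp_path} lacks columns {sorted(missing_cols)}")
        if list(snps["id"]) != list(df.columns):
            raise ParseError("SNP table ids do not match dosage columns")
    else:  # synthesize minimal coordinates: one chromosome, consecutive positions
        snps = pd.DataFrame(
            dict(id=df.columns, chrom="chr1", pos=np.arange(1, df.shape[1] + 1),
                 ref="A", alt="B")
        )
    if sample_path is not None:
        samples = pd.read_csv(sample_path, sep="\t")
        if list(samples["id"].astype(str)) != [str(i) for i in df.index]:
            raise ParseError("sample table ids do not match dosage rows")
    else:
        samples = pd.DataFrame(dict(id=df.index.astype(str), population="pop0"))
    return GenotypePanel(df.to_numpy(dtype=float), snps, samples)


def write_expression_tsv(expr: ExpressionPanel, path, gene_path=None) -> None:
    df = pd.DataFrame(expr.values, index=expr.sample_ids, columns=expr.gene_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.6f")
    if gene_path is not None:
        expr.genes.to_csv(gene_path, sep="\t", index=False)


def read_expression_tsv(path, gene_path) -> ExpressionPanel:
    _check_unique_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    genes = pd.read_csv(gene_path, sep="\t")
    missing_cols = set(GENE_COLUMNS) - set(genes.columns)
    if missing_cols:
        raise ParseError(f"gene table {gene_path} lacks columns {sorted(missing_cols)}")
    if list(genes["id"]) != list(df.columns):
        raise ParseError("gene annotation ids do not match expression columns")
    return ExpressionPanel(df.to_numpy(dtype=float), genes, df.index.to_numpy())


WEIGHT_COLUMNS = ["gene", "snp", "alt", "weight", "method", "lambda", "alpha", "intercept"]


def write_weights_tsv(models, path) -> None:
    """Serialize linear GeneModels (dosage-scale weights) to one TSV."""
    rows = []
    for m in models:
        if not m.weight_representable:
            logger.warning("model %s/%s is not weight-representable; skipped", m.gene, m.method)
            continue
        w = m.weights_dosage
        icept = m.intercept_dosage
        lam = m.tuning.get("lambda", np.nan)
        alp = m.tuning.get("alpha", np.nan)
        for s, a, wj in zip(m.snp_ids, m.alt, w):
            rows.append((m.gene, s, a, wj, m.method, lam, alp, icept))
    pd.DataFrame(rows, columns=WEIGHT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def read_weights_tsv(path) -> dict[str, GeneModel]:
    df = pd.read_csv(path, sep="\t")
    missing_cols = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"weight table {path} lacks columns {sorted(missing_cols)}")
    models: dict[str, GeneModel] = {}
    for (gene, method), sub in df.groupby(["gene", "method"], sort=False):
        if gene in models:
            raise ParseError(f"gene {gene!r} appears under multiple methods in {path}")
        p = len(sub)
        models[gene] = GeneModel(
            gene=gene,
            method=method,
            snp_ids=sub["snp"].to_numpy(),
            alt=sub["alt"].to_numpy(),
            weights_std=sub["weight"].to_numpy(dtype=float),  # dosage scale...
            center=np.zeros(p),
            scale=np.ones(p),  # ...expressed as std-scale with identity stats
            y_mean=float(sub["intercept"].iloc[0]),
            tuning={"lambda": float(sub["lambda"].iloc[0]),
                    "alpha": float(sub["alpha"].iloc[0])},
        )
    return models
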