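"""Quantitative-trait SNP association for the asymmetry phenotype scores.

A from-scratch linear-model scan: minor-allele-carrier filtering, genotype
principal components as ancestry covariates, per-SNP ordinary least squares
of the score on [1, genotype, age, sex, PCs] with a two-sided t-test on the
genotype coefficient, Benjamini–Hochberg step-up FDR adjustment pooled
globally across phenotypes, and Pearson/Kendall covariate screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "AssocStats",
    "read_genotype_tsv",
    "read_plink_text",
    "mac_filter",
    "genotype_pcs",
    "linear_assoc",
    "association_scan",
    "bh_adjust",
    "covariate_tests",
    "manhattan_table",
]

GENOME_WIDE_SIGNIFICANCE = 5e-8
SUGGESTIVE_SIGNIFICANCE = 1e-5


@dataclass
class GenotypeMatrix:
    """Additive genotype codes (subjects x SNPs) with SNP metadata.

    ``codes`` holds 0/1/2 copies of the minor-by-file allele as float with
    NaN for missing; ``info`` is indexed by SNP id with ``chrom``/``pos``.
    """

    codes: pd.DataFrame
    info: pd.DataFrame

    def __post_init__(self) -> None:
        if self.codes.index.has_duplicates:
            raise ValueError("duplicate subject IDs in genotype matrix")
        vals = self.codes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")
        missing_info = set(self.codes.columns) - set(self.info.index)
        if missing_info:
            raise ValueError(f"SNPs without metadata: {sorted(missing_info)[:5]}")

    @property
    def n_subjects(self) -> int:
        return len(self.codes)

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def subset(self, snps) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes[list(snps)], self.info.loc[list(snps)])


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read the simple TSV dialect: rows = subjects, header = SNP ids, values 0/1/2/NA.

    Optional companion metadata columns may be supplied via a header of the
    form ``snp:chrom:pos``; otherwise chrom/pos default to 0.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "nan", ""])
    names, chroms, poss = [], [], []
    for col in df.columns:
        parts = str(col).split(":")
        names.append(parts[0])
        chroms.append(int(parts[1]) if len(parts) > 1 else 0)
        poss.append(int(parts[2]) if len(parts) > 2 else 0)
    df.columns = names
    info = pd.DataFrame({"chrom": chroms, "pos": poss}, index=names)
    return GenotypeMatrix(df.astype(float), info)


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    codes = gm.codes.copy()
    codes.columns = [f"{s}:{gm.info.loc[s, 'chrom']}:{gm.info.loc[s, 'pos']}" for s in codes.columns]
    codes.to_csv(path, sep="\t", na_rep="NA")


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK-style text .ped/.map files (biallelic SNPs, '0 0' missing).

    Codes count copies of the minor allele as determined from the sample.
    """
    snps = pd.read_csv(map_path, sep=r"\s+", header=None,
                       names=["chrom", "snp", "cm", "pos"])
    rows, ids = [], []
    with open(ped_path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            ids.append(tok[1])  # within-family ID
            alleles = tok[6:]
            if len(alleles) != 2 * len(snps):
                raise ValueError(
                    f".ped row for {tok[1]} has {len(alleles)} allele fields, "
                    f"expected {2 * len(snps)}")
            rows.append(alleles)
    raw = np.array(rows, dtype=object).reshape(len(ids), len(snps), 2)
    codes = np.full((len(ids), len(snps)), np.nan)
    for j in range(len(snps)):
        col = raw[:, j, :]
        present = col[col != "0"]
        alleles = pd.unique(present)
        if len(alleles) > 2:
            raise ValueError(f"SNP {snps.snp[j]} has >2 alleles: {list(alleles)}")
        if len(alleles) == 0:
            continue
        counts = {a: (present == a).sum() for a in alleles}
        minor = min(counts, key=lambda a: (counts[a], str(a)))
        valid = (col != "0").all(axis=1)
        codes[valid, j] = (col[valid] == minor).sum(axis=1)
    df = pd.DataFrame(codes, index=ids, columns=snps.snp)
    info = snps.set_index("snp")[["chrom", "pos"]]
    return GenotypeMatrix(df, info)


# ---------------------------------------------------------------------------
# Filtering and ancestry PCs
# ---------------------------------------------------------------------------

def mac_filter(genotypes: GenotypeMatrix, min_subjects: int = 5,
               mode: str = "carrier") -> GenotypeMatrix:
    """Drop SNPs whose minor allele is present in too few subjects.

    ``mode='carrier'`` (default, the literal reading of "present in fewer
    than N subjects") counts subjects carrying >= 1 copy of the minor
    allele; ``mode='allele'`` counts allele copies instead. The minor allele
    is determined per SNP from the sample frequency.
    """
    if mode not in ("carrier", "allele"):
        raise ValueError("mode must be 'carrier' or 'allele'")
    g = genotypes.codes.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g, axis=0) / 2.0
    flipped = np.where(np.nan_to_num(freq) > 0.5, 2.0 - g, g)  # minor-allele dosage
    if mode == "carrier":
        count = np.nansum(flipped >= 1, axis=0)
    else:
        count = np.nansum(flipped, axis=0)
    keep = genotypes.codes.columns[count >= min_subjects]
    if len(keep) == 0:
        import warnings
        warnings.warn("minor-allele filter removed every SNP", stacklevel=2)
    return genotypes.subset(keep)


def genotype_pcs(genotypes: GenotypeMatrix, k: int = 4) -> pd.DataFrame:
    """Top-k principal-component scores of the standardized genotype matrix.

    Missing codes are mean-imputed, columns are centred and scaled to unit
    variance (monomorphic columns are skipped). The sign of each component
    is fixed by forcing its largest-magnitude SNP loading positive, so the
    decomposition is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = genotypes.codes.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    X = X[:, sd > 0] / sd[sd > 0]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((S > S[0] * 1e-10).sum()) if len(S) else 0
    if k > rank:
        raise ValueError(f"requested {k} PCs but genotype matrix has rank {rank}")
    scores = U[:, :k] * S[:k]
    for j in range(k):
        i_max = np.abs(Vt[j]).argmax()
        if Vt[j, i_max] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, index=genotypes.codes.index,
                        columns=[f"PC{i + 1}" for i in range(k)])


# ---------------------------------------------------------------------------
# Linear model
# ---------------------------------------------------------------------------

@dataclass
class AssocStats:
    beta: float
    se: float
    t: float
    p: float
    n: int


def _check_collinear(X: np.ndarray, names: list[str]) -> None:
    """Raise naming the first column lying in the span of the previous ones."""
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, :j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
            raise ValueError(f"collinear design: column '{names[j]}' is linearly "
                             "dependent on the preceding columns")


def linear_assoc(phenotype: np.ndarray, genotype_col: np.ndarray,
                 covariates: np.ndarray | pd.DataFrame | None = None) -> AssocStats:
    """OLS of the score on [1, genotype, covariates]; two-sided t-test on beta_g.

    Subjects with a missing genotype or covariate are dropped (per-SNP
    complete cases).
    """
    y = np.asarray(phenotype, dtype=float).reshape(-1)
    g = np.asarray(genotype_col, dtype=float).reshape(-1)
    cov_names: list[str] = []
    if covariates is None:
        C = np.empty((len(y), 0))
    else:
        if isinstance(covariates, pd.DataFrame):
            cov_names = [str(c) for c in covariates.columns]
            C = covariates.to_numpy(dtype=float)
        else:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != len(y):
                C = C.T
            cov_names = [f"cov{i}" for i in range(C.shape[1])]
    ok = np.isfinite(y) & np.isfinite(g) & np.isfinite(C).all(axis=1)
    y, g, C = y[ok], g[ok], C[ok]
    n = len(y)
    p_cols = 2 + C.shape[1]
    if n <= p_cols:
        raise ValueError(f"too few complete cases ({n}) for {p_cols} parameters")
    X = np.column_stack([np.ones(n), g, C])
    names = ["intercept", "genotype", *cov_names]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _check_collinear(X, names)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    t = float(beta[1] / se) if se > 0 else np.inf * np.sign(beta[1])
    p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return AssocStats(float(beta[1]), se, t, max(p, np.nextafter(0, 1)), n)


def _scan_complete(y: np.ndarray, G: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized per-SNP OLS via Frisch–Waugh–Lovell for complete data.

    Residualizing y and every genotype column on the covariate block gives
    exactly the full-design OLS genotype coefficient, SE and t statistic.
    """
    n = len(y)
    Q, _ = np.linalg.qr(C)
    My = y - Q @ (Q.T @ y)
    MG = G - Q @ (Q.T @ G)
    gg = np.einsum("ij,ij->j", MG, MG)
    gy = MG.T @ My
    df = n - C.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = float(My @ My) - beta * gy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    bad = gg <= 1e-12  # monomorphic after residualization
    beta[bad], se[bad], t[bad], p[bad] = np.nan, np.nan, np.nan, 1.0
    return beta, se, t, np.maximum(p, np.nextafter(0, 1))


def association_scan(phenotypes: pd.DataFrame, genotypes: GenotypeMatrix,
                     covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-SNP linear association for each phenotype column, globally BH-adjusted.

    Returns a tidy table with columns PHENO, SNP, CHR, POS, BETA, SE, T, P,
    N and P_FDR, where the FDR adjustment pools the raw p-values of all
    phenotypes into one family.
    """
    subjects = phenotypes.index
    if not subjects.equals(genotypes.codes.index):
        raise ValueError("phenotype and genotype subject IDs do not match")
    C_df = covariates.loc[subjects] if covariates is not None else None
    G = genotypes.codes.to_numpy(dtype=float)
    has_missing = np.isnan(G).any(axis=0)
    C = np.column_stack([np.ones(len(subjects)),
                         C_df.to_numpy(dtype=float) if C_df is not None else np.empty((len(subjects), 0))])
    blocks = []
    for pheno in phenotypes.columns:
        y = phenotypes[pheno].to_numpy(dtype=float)
        beta, se, t, p, n_used = (np.empty(genotypes.n_snps) for _ in range(5))
        complete = ~has_missing
        if complete.any():
            b, s, tt, pp = _scan_complete(y, G[:, complete], C)
            beta[complete], se[complete], t[complete], p[complete] = b, s, tt, pp
            n_used[complete] = len(y)
        for j in np.flatnonzero(has_missing):
            st = linear_assoc(y, G[:, j], C[:, 1:] if C.shape[1] > 1 else None)
            beta[j], se[j], t[j], p[j], n_used[j] = st.beta, st.se, st.t, st.p, st.n
        blocks.append(pd.DataFrame({
            "PHENO": pheno,
            "SNP": genotypes.codes.columns,
            "CHR": genotypes.info["chrom"].to_numpy(),
            "POS": genotypes.info["pos"].to_numpy(),
            "BETA": beta, "SE": se, "T": t, "P": p, "N": n_used.astype(int),
        }))
    out = pd.concat(blocks, ignore_index=True)
    out["P_FDR"] = bh_adjust(out["P"].to_numpy())
    return out


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1, returned in the input
    order. Intended to be applied to the pooled p-vector across phenotypes.
    """
    p = np.asarray(pvalues, dtype=float).reshape(-1)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def covariate_tests(scores: np.ndarray, age: np.ndarray, sex: np.ndarray) -> dict[str, float]:
    """Pearson test of score vs age and Kendall tau-b test of score vs sex.

    Kendall's rank test makes no normality assumption, which suits the
    dichotomous sex covariate (coded 0/1; the sign of tau follows the coding).
    """
    s = np.asarray(scores, float)
    a = np.asarray(age, float)
    x = np.asarray(sex, float)
    if len(s) < 3:
        raise ValueError("covariate tests need n >= 3")
    for name, arr in (("scores", s), ("age", a), ("sex", x)):
        if np.ptp(arr) == 0:
            raise ValueError(f"constant input vector: {name}")
    r, rp = stats.pearsonr(s, a)
    tau, taup = stats.kendalltau(s, x)
    return {"pearson_r": float(r), "pearson_p": float(rp),
            "kendall_tau": float(tau), "kendall_p": float(taup)}


def manhattan_table(results: pd.DataFrame,
                    significance: float = GENOME_WIDE_SIGNIFICANCE,
                    suggestive: float = SUGGESTIVE_SIGNIFICANCE,
                    plot_path=None) -> pd.DataFrame:
    """Rank association results by p-value and flag threshold crossings.

    Optionally renders a Manhattan plot (-log10 p by genomic position) to
    ``plot_path``.
    """
    out = results.sort_values("P", kind="stable").reset_index(drop=True)
    out["SIGNIFICANT"] = out["P"] < significance
    out["SUGGESTIVE"] = (out["P"] < suggestive) & ~out["SIGNIFICANT"]
    if plot_path is not None and len(out):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(9, 3.5))
        chroms = sorted(out["CHR"].unique())
        offset, ticks = 0.0, []
        for c in chroms:
            sub = out[out["CHR"] == c]
            x = offset + (sub["POS"] - sub["POS"].min()).to_numpy(dtype=float)
            ax.scatter(x, -np.log10(sub["P"]), s=6,
                       color="tab:blue" if chroms.index(c) % 2 == 0 else "tab:cyan")
            ticks.append((offset + x.max()) / 2 if len(x) else offset)
            offset = (x.max() if len(x) else offset) + 1.0
        ax.axhline(-np.log10(significance), color="red", lw=0.8)
        ax.axhline(-np.log10(suggestive), color="blue", lw=0.8)
        ax.set_xticks(ticks, [str(c) for c in chroms])
        ax.set_xlabel("chromosome")
        ax.set_ylabel(r"$-\log_{10} p$")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return out
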