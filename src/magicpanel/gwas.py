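"""Mixed-linear-model association scan with kinship and structure covariates.

The model for a quantitative trait y over n lines is

    y = 1*mu + Q*v + x*beta + u + e,   u ~ N(0, sg2 * K),  e ~ N(0, se2 * I)

with K a VanRaden-type genomic relationship matrix, Q optional structure
covariates, and x the marker dosage under test.  Variance components are
estimated once by REML on the null model (no marker) via the spectral
decomposition of K with a 1-D search over the variance ratio
delta = se2/sg2, then reused for every marker (the P3D strategy), so each
marker test is a generalized least squares fit with a Wald t test on beta.

:class:`MixedLMScan` is the model object; :meth:`MixedLMScan.fit` returns a
:class:`ScanResults` carrying per-marker -log10 p and additive effects
(alt-allele dosage sign convention), a `summary()` table, thresholds and
plots.  The module-level :func:`mlm_scan` is a convenience wrapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING

DELTA_BOUNDS = (1e-5, 1e5)
_REML_TOL = 1e-8


class KinshipError(ValueError):
    pass


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix (symmetric PSD, diagonal ~ 1 + inbreeding)."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.samples),) * 2:
            raise ValueError("kinship shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("kinship not symmetric")
        w = np.linalg.eigvalsh(v)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise KinshipError(f"kinship not PSD (min eigenvalue {w.min():.3g})")
        self.values = (v + v.T) / 2


def kinship(matrix: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden centered cross-product estimator K = W W' / c.

    W is the column-centered dosage matrix (missing imputed by site mean)
    and c = sum over sites of 2 p (1 - p) with p the alt-allele frequency.
    Monomorphic-only input has c = 0 and raises.
    """
    d = matrix.dosage(impute=True)  # sites x samples
    p = d.mean(axis=1) / 2.0
    c = float(np.sum(2.0 * p * (1.0 - p)))
    if c <= 0:
        raise KinshipError("all sites monomorphic; kinship undefined")
    W = (d - d.mean(axis=1, keepdims=True)).T  # samples x sites
    return KinshipMatrix(list(matrix.samples), W @ W.T / c)


def bonferroni_threshold(alpha: float, n: int) -> float:
    """Genome-wide -log10 significance cutoff, -log10(alpha / n)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    return -math.log10(alpha / n)


# ---------------------------------------------------------------------------
# Model / results


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float

    @property
    def delta(self) -> float:
        return self.sigma2_e / self.sigma2_g

    @property
    def heritability(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


class MixedLMScan:
    """Single-marker mixed-model association scan over a genotype matrix.

    Parameters
    ----------
    phenotype : array of length n_samples (aligned with ``genotypes.samples``)
    genotypes : GenotypeMatrix of the markers to test
    covariates : optional n x q structure covariates (Q), without intercept
    kin : optional KinshipMatrix; identity yields ordinary regression
    trait : trait name carried into results
    """

    def __init__(self, phenotype, genotypes: GenotypeMatrix,
                 covariates: np.ndarray | None = None,
                 kin: KinshipMatrix | None = None, trait: str = "trait"):
        y = np.asarray(phenotype, float)
        if y.ndim != 1 or y.size != genotypes.n_samples:
            raise ValueError("phenotype length does not match samples")
        if np.ptp(y) == 0:
            raise ValueError("phenotype is constant")
        if np.any(np.isnan(y)):
            raise ValueError("phenotype contains NaN")
        self.y = y
        self.genotypes = genotypes
        n = genotypes.n_samples
        X = [np.ones((n, 1))]
        if covariates is not None:
            Qm = np.atleast_2d(np.asarray(covariates, float))
            if Qm.shape[0] != n:
                Qm = Qm.T
            X.append(Qm)
        self.X0 = np.hstack(X)
        if kin is not None and kin.samples != genotypes.samples:
            raise ValueError("kinship samples misaligned with genotypes")
        self.kin = kin
        self.trait = trait

    @classmethod
    def from_dataframe(cls, pheno: pd.DataFrame, trait: str,
                       genotypes: GenotypeMatrix,
                       covariates: np.ndarray | None = None,
                       kin: KinshipMatrix | None = None) -> "MixedLMScan":
        """Build from a phenotype table indexed by sample id."""
        y = pheno.loc[genotypes.samples, trait].to_numpy(float)
        return cls(y, genotypes, covariates, kin, trait=trait)

    # -- REML ------------------------------------------------------------

    def _decompose(self):
        n = len(self.y)
        if self.kin is None:
            return np.ones(n), np.eye(n)
        lam, U = np.linalg.eigh(self.kin.values)
        return np.clip(lam, 0.0, None), U

    def _reml_delta(self, lam: np.ndarray, U: np.ndarray) -> VarianceComponents:
        y = U.T @ self.y
        X = U.T @ self.X0
        n, p = X.shape
        XtX0 = self.X0.T @ self.X0
        _, logdet_xx = np.linalg.slogdet(XtX0)

        def neg_restricted_ll(log_delta: float) -> float:
            delta = math.exp(log_delta)
            w = lam + delta
            Xw = X / w[:, None]
            XtHX = X.T @ Xw
            beta = np.linalg.solve(XtHX, Xw.T @ y)
            r = y - X @ beta
            rss = float(np.sum(r * r / w))
            sg2 = rss / (n - p)
            _, logdet_xhx = np.linalg.slogdet(XtHX)
            ll = -0.5 * ((n - p) * math.log(2 * math.pi * sg2) + (n - p)
                         + float(np.sum(np.log(w))) + logdet_xhx - logdet_xx)
            return -ll

        res = optimize.minimize_scalar(
            neg_restricted_ll,
            bounds=(math.log(DELTA_BOUNDS[0]), math.log(DELTA_BOUNDS[1])),
            method="bounded", options={"xatol": _REML_TOL},
        )
        delta = math.exp(res.x)
        w = lam + delta
        Xw = X / w[:, None]
        beta = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        r = y - X @ beta
        sg2 = float(np.sum(r * r / w)) / (len(y) - X.shape[1])
        return VarianceComponents(sigma2_g=sg2, sigma2_e=sg2 * delta)

    # -- fitting ----------------------------------------------------------

    def fit(self, delta: float | None = None) -> "ScanResults":
        """REML on the null model once, then per-marker GLS (P3D).

        ``delta`` fixes the variance ratio sigma2_e/sigma2_g instead of
        estimating it (delta -> inf recovers fixed-effects regression).
        """
        lam, U = self._decompose()
        if self.kin is None:
            vc = None
            w = np.ones_like(lam)
        elif delta is not None:
            vc = VarianceComponents(sigma2_g=1.0, sigma2_e=delta)
            w = lam + delta
        else:
            vc = self._reml_delta(lam, U)
            w = lam + vc.delta
        sw = 1.0 / np.sqrt(w)
        yt = (U.T @ self.y) * sw
        X0t = (U.T @ self.X0) * sw[:, None]
        G = self.genotypes.dosage(impute=True)  # sites x samples
        Gt = (G @ U) * sw[None, :]  # sites x samples, rotated

        n, p = X0t.shape
        XtX = X0t.T @ X0t
        XtXinv = np.linalg.inv(XtX)
        H0 = X0t @ XtXinv  # n x p
        ymr = yt - H0 @ (X0t.T @ yt)  # M0 y
        y_rss0 = float(yt @ ymr)
        Gm = Gt.T - H0 @ (X0t.T @ Gt.T)  # M0 x per marker (n x m)
        xMx = np.einsum("ij,ij->j", Gm, Gm)
        xMy = Gm.T @ ymr
        df = n - p - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = xMy / xMx
            rss = y_rss0 - xMy * beta
            sigma2 = rss / df
            tstat = beta / np.sqrt(sigma2 / xMx)
        # markers collinear with the fixed effects are skipped (flagged NaN);
        # the criterion is scale-free: residual variance relative to x'x
        xtx = np.einsum("ij,ij->i", Gt, Gt)
        with np.errstate(divide="ignore", invalid="ignore"):
            near_zero = (xtx <= 0) | (xMx <= 1e-10 * xtx)
        tstat[near_zero] = np.nan
        beta[near_zero] = np.nan
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        neg_log10 = -np.log10(np.clip(pvals, 1e-300, None))
        neg_log10[np.isnan(tstat)] = np.nan
        table = pd.DataFrame({
            "site_id": [s.site_id for s in self.genotypes.sites],
            "chrom": [s.chrom for s in self.genotypes.sites],
            "pos": [s.pos for s in self.genotypes.sites],
            "trait": self.trait,
            "neg_log10_p": neg_log10,
            "add_effect": beta,
            "p_value": pvals,
            "skipped": near_zero,
        })
        return ScanResults(self, table, vc, df)


@dataclass
class ScanResults:
    """Per-marker association results of a :class:`MixedLMScan` fit."""

    model: MixedLMScan
    table: pd.DataFrame
    variance_components: VarianceComponents | None
    df_resid: int

    @property
    def neg_log10_p(self) -> np.ndarray:
        return self.table["neg_log10_p"].to_numpy()

    @property
    def add_effect(self) -> np.ndarray:
        return self.table["add_effect"].to_numpy()

    @property
    def n_markers(self) -> int:
        return int((~self.table["skipped"]).sum())

    def threshold(self, alpha: float = 0.05) -> float:
        """Bonferroni -log10 cutoff at level alpha over the tested markers."""
        return bonferroni_threshold(alpha, self.n_markers)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        thr = self.threshold(alpha)
        t = self.table
        return t[t["neg_log10_p"] >= thr].reset_index(drop=True)

    def summary(self, alpha: float = 0.05) -> str:
        lines = [
            f"Mixed linear model scan — trait {self.model.trait!r}",
            f"  samples: {len(self.model.y)}   markers tested: {self.n_markers}",
        ]
        if self.variance_components is not None:
            vc = self.variance_components
            lines.append(
                f"  REML variance components: sigma2_g={vc.sigma2_g:.4g} "
                f"sigma2_e={vc.sigma2_e:.4g} (h2={vc.heritability:.3f})")
        else:
            lines.append("  no kinship supplied: ordinary least squares scan")
        thr = self.threshold(alpha)
        sig = self.significant(alpha)
        lines.append(f"  Bonferroni threshold (-log10): {thr:.4f} at alpha={alpha}")
        lines.append(f"  significant markers: {len(sig)}")
        top = self.table.sort_values("neg_log10_p", ascending=False).head(5)
        lines.append("  top hits:")
        for _, r in top.iterrows():
            lines.append(
                f"    {r.site_id} {r.chrom}:{r.pos} -log10p={r.neg_log10_p:.2f} "
                f"effect={r.add_effect:+.3f}")
        return "\n".join(lines)

    def manhattan(self, ax=None, alpha: float = 0.05):
        """Manhattan plot (cosmetic); returns the matplotlib axis."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0
        t = self.table.dropna(subset=["neg_log10_p"])
        for i, (chrom, grp) in enumerate(t.groupby("chrom", sort=True)):
            ax.scatter(grp["pos"] + offset, grp["neg_log10_p"], s=4,
                       color=["#3b6fb6", "#9dbce0"][i % 2])
            offset += grp["pos"].max()
        ax.axhline(self.threshold(alpha), color="red", lw=0.8, ls="--")
        ax.set_xlabel("genome position")
        ax.set_ylabel("-log10 p")
        ax.set_title(self.model.trait)
        return ax


def mlm_scan(genotypes: GenotypeMatrix, phenotype, Q=None,
             K: KinshipMatrix | None = None, trait: str = "trait") -> ScanResults:
    """Convenience wrapper: build a :class:`MixedLMScan` and fit it."""
    return MixedLMScan(phenotype, genotypes, Q, K, trait=trait).fit()


# ---------------------------------------------------------------------------
# Multi-trait hits, regions, candidate genes


def multi_trait_hits(results: dict[str, ScanResults], threshold: float,
                     min_traits: int = 2) -> list[tuple[str, frozenset]]:
    """Sites significant (neg_log10_p >= threshold) in at least ``min_traits`` traits.

    Returns (site_id, qualifying trait set), ordered by genome position.
    """
    by_site: dict[str, set] = {}
    pos: dict[str, tuple] = {}
    for trait, res in results.items():
        t = res.table
        sig = t[t["neg_log10_p"] >= threshold]
        for _, r in sig.iterrows():
            by_site.setdefault(r.site_id, set()).add(trait)
            pos[r.site_id] = (r.chrom, r.pos)
    hits = [(sid, frozenset(traits)) for sid, traits in by_site.items()
            if len(traits) >= min_traits]
    hits.sort(key=lambda h: pos[h[0]])
    return hits


@dataclass
class Region:
    """A run of significant sites chained by physical proximity."""

    chrom: str
    start: int
    end: int
    sites: list

    @property
    def span_mb(self) -> float:
        return round((self.end - self.start) / 1e6, 2)


def build_regions(hits: list[tuple[str, int]], max_gap: int = 1_000_000
                  ) -> list[Region]:
    """Single-linkage chaining of (chrom, pos) hits within ``max_gap`` bp.

    Idempotent and independent of input order (hits are sorted first).
    """
    ordered = sorted(hits)
    regions: list[Region] = []
    for chrom, pos in ordered:
        if (regions and regions[-1].chrom == chrom
                and pos - regions[-1].end <= max_gap):
            regions[-1].end = max(regions[-1].end, pos)
            regions[-1].sites.append((chrom, pos))
        else:
            regions.append(Region(chrom, pos, pos, [(chrom, pos)]))
    return regions


def candidate_genes(region: Region, gene_db) -> list[str]:
    """Gene IDs whose span overlaps the region (1-based inclusive, no flank)."""
    out = []
    for g in gene_db.region(region=(region.chrom, region.start - 1, region.end),
                            completely_within=False):
        if g.featuretype == "gene" and g.start <= region.end and g.end >= region.start:
            out.append(g.id)
    return sorted(set(out))


# ---------------------------------------------------------------------------
# Genotype-class contrast


@dataclass
class ContrastResult:
    groups: dict[str, tuple[int, float, float]]  # label -> (n, mean, sd)
    t_stat: float
    p_value: float
    mean_difference: float


def genotype_contrast(genotypes: GenotypeMatrix, site_id: str, phenotype,
                      condition: tuple[str, int] | None = None
                      ) -> ContrastResult:
    """Welch two-sample test between the homozygote classes at one site.

    ``condition`` optionally restricts to samples with a given genotype
    code at another site (e.g. the common background at a second locus).
    Heterozygous and missing calls are excluded from the contrast.
    """
    y = np.asarray(phenotype, float)
    i = genotypes.site_index_by_id(site_id)
    calls = genotypes.calls[i]
    keep = np.ones(genotypes.n_samples, bool)
    if condition is not None:
        j = genotypes.site_index_by_id(condition[0])
        keep &= genotypes.calls[j] == condition[1]
    g_ref = keep & (calls == HOM_REF)
    g_alt = keep & (calls == HOM_ALT)
    if g_ref.sum() == 0 or g_alt.sum() == 0:
        raise ValueError(
            f"a homozygote class at {site_id} is empty after conditioning "
            f"(ref n={int(g_ref.sum())}, alt n={int(g_alt.sum())})")
    a, b = y[g_ref], y[g_alt]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    groups = {
        "hom_ref": (int(a.size), float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0),
        "hom_alt": (int(b.size), float(b.mean()), float(b.std(ddof=1)) if b.size > 1 else 0.0),
    }
    return ContrastResult(groups, float(t), float(p), float(b.mean() - a.mean()))
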