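"""Strand-aware beta-binomial caller for subclonal somatic variants.

Deep targeted sequencing of normal tissue detects mutant clones at allele
fractions far below the germline 0.5, where the background error rate (a
mixture of sequencing and PCR artefacts) is the limiting factor.  The
error rate varies along the genome, and genuine mutations are present
equally on both strands whereas PCR errors favour one strand.  Both
properties are exploited here:

* the background at each site/allele/strand is modelled as beta-binomial
  with a site-specific mean error fraction (estimated across a panel of
  control samples) and a single genome-wide overdispersion ρ;
* a likelihood-ratio test contrasts the strand-specific background (null)
  against a shared per-site variant allele fraction on both strands
  (alternative), with the statistic referred to χ² on 2 degrees of
  freedom;
* Benjamini–Hochberg correction (q < 0.05), removal of variants also
  present in the matched control, coverage (>50 total reads in sample and
  control), support (≥5 reads) and 5-bp merge filters follow.

Beta-binomial parameterisation: mean μ and intraclass correlation ρ map to
shape parameters α = μ(1−ρ)/ρ, β = (1−μ)(1−ρ)/ρ; ρ→0 recovers the
binomial and μ=0 a point mass at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

ALLELES = ("A", "C", "G", "T", "-")
_ALLELE_IDX = {a: i for i, a in enumerate(ALLELES)}


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Per sample × position × allele × strand read counts.

    counts: int array (n_samples, n_positions, 5 alleles [A,C,G,T,−], 2 strands);
    coverage: int array (n_samples, n_positions, 2 strands).
    positions: DataFrame with columns chrom, pos (1-based), ref.
    """

    samples: list[str]
    positions: pd.DataFrame
    counts: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        s, p = len(self.samples), len(self.positions)
        if self.counts.shape != (s, p, len(ALLELES), 2):
            raise ValueError(f"counts shape {self.counts.shape} inconsistent "
                             f"with {s} samples × {p} positions")
        if self.coverage.shape != (s, p, 2):
            raise ValueError("coverage shape inconsistent")
        if np.any(self.counts < 0):
            raise ValueError("negative read counts")
        if np.any(self.counts.sum(axis=2) > self.coverage):
            raise ValueError("allele counts exceed strand coverage")

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    @property
    def ref_index(self) -> np.ndarray:
        return self.positions["ref"].map(_ALLELE_IDX).to_numpy()


# ---------------------------------------------------------------------------
# Beta-binomial likelihood
# ---------------------------------------------------------------------------

def betabin_loglik(x, n, mu, rho):
    """Log pmf of the beta-binomial with mean ``mu`` and overdispersion ``rho``.

    Vectorised over all arguments.  μ=0 (or 1) is the degenerate point mass
    at 0 (or n).  ρ must be in (0, 1); small ρ approaches the binomial.
    """
    x = np.asarray(x, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    if np.any(x > n) or np.any(x < 0):
        raise ValueError("require 0 <= x <= n")
    if np.any((mu < 0) | (mu > 1)):
        raise ValueError("mu must lie in [0, 1]")
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    x, n, mu = np.broadcast_arrays(x, n, mu)
    out = np.empty(x.shape, dtype=np.float64)
    lo = mu == 0.0
    hi = mu == 1.0
    out[lo] = np.where(x[lo] == 0, 0.0, -np.inf)
    out[hi] = np.where(x[hi] == n[hi], 0.0, -np.inf)
    mid = ~(lo | hi)
    if np.any(mid):
        a = mu[mid] * (1.0 - rho) / rho
        b = (1.0 - mu[mid]) * (1.0 - rho) / rho
        out[mid] = stats.betabinom.logpmf(x[mid], n[mid], a, b)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Error model
# ---------------------------------------------------------------------------

@dataclass
class ErrorModel:
    """Background error model fitted on control samples.

    v: per-position per-allele per-strand mean error fraction, shape
    (n_positions, 5, 2), pooled across controls; rho: single genome-wide
    overdispersion; min_error: floor applied to v when testing (sites with
    zero observed control errors still have a nonzero true error rate).
    """

    positions: pd.DataFrame
    v: np.ndarray
    rho: float
    min_error: float = 1e-5
    excluded: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def v_tested(self) -> np.ndarray:
        """Error fractions floored at min_error, as used by the LRT."""
        return np.maximum(self.v, self.min_error)


RHO_BOUNDS = (1e-6, 0.5)


def fit_error_model(control_counts: CountMatrix, min_error: float = 1e-5,
                    pooled: bool = True, rho_grid_size: int = 25) -> ErrorModel:
    """Fit per-site strand-specific error fractions and a shared overdispersion.

    v is the pooled read fraction across controls per site/allele/strand
    (set ``pooled=False`` for the mean of per-sample fractions).  ρ is
    fitted by profile likelihood over all non-reference site/allele/strand
    cells jointly: a log-spaced grid on [1e-6, 0.5] followed by bounded
    local refinement.  Sites with zero total control coverage on a strand
    are flagged in ``excluded`` and not used for ρ.
    """
    if len(control_counts.samples) < 2:
        raise ValueError("need at least 2 control samples")
    counts = control_counts.counts
    cov = control_counts.coverage
    pooled_counts = counts.sum(axis=0).astype(np.float64)      # (P, 5, 2)
    pooled_cov = cov.sum(axis=0).astype(np.float64)            # (P, 2)
    zero_cov = pooled_cov == 0
    safe_cov = np.where(zero_cov, 1.0, pooled_cov)
    if pooled:
        v = pooled_counts / safe_cov[:, None, :]
    else:
        frac = counts / np.maximum(cov, 1)[:, :, None, :]
        v = frac.mean(axis=0)
    v[np.broadcast_to(zero_cov[:, None, :], v.shape)] = np.nan

    # rho: joint profile likelihood over non-reference cells with v > 0
    ref_idx = control_counts.ref_index
    alt_mask = np.ones((len(control_counts.positions), len(ALLELES)), dtype=bool)
    alt_mask[np.arange(len(ref_idx)), ref_idx] = False
    cell_mask = alt_mask[:, :, None] & ~zero_cov[:, None, :] & (v > 0)
    x = counts[:, cell_mask].ravel()
    n = np.broadcast_to(cov[:, :, None, :], counts.shape)[:, cell_mask].ravel()
    mu = np.broadcast_to(v, counts.shape[1:])[cell_mask]
    mu = np.tile(mu, len(control_counts.samples))

    def nll(log_rho: float) -> float:
        return -float(np.sum(betabin_loglik(x, n, mu, np.exp(log_rho))))

    lo, hi = np.log(RHO_BOUNDS[0]), np.log(RHO_BOUNDS[1])
    if x.size == 0:
        rho = RHO_BOUNDS[0]
    else:
        grid = np.linspace(lo, hi, rho_grid_size)
        vals = [nll(g) for g in grid]
        i = int(np.argmin(vals))
        a, b = grid[max(i - 1, 0)], grid[min(i + 1, rho_grid_size - 1)]
        res = optimize.minimize_scalar(nll, bounds=(a, b), method="bounded")
        rho = float(np.exp(res.x))
    excluded = zero_cov.any(axis=1)
    return ErrorModel(positions=control_counts.positions, v=v, rho=rho,
                      min_error=min_error, excluded=excluded)


# ---------------------------------------------------------------------------
# Likelihood-ratio test
# ---------------------------------------------------------------------------

def lrt_site(x, xp, n, np_, v, vp, rho):
    """Strand-aware likelihood-ratio p-value for one site/allele (vectorised).

    Null: forward/reverse counts follow the strand-specific backgrounds
    (v, v').  Alternative: both strands share the pooled variant fraction
    μ = (x + x')/(n + n').  LR = 2(ℓ₁ − ℓ₀), floored at 0, referred to
    χ²(2 df).
    """
    x = np.asarray(x, dtype=np.float64)
    xp = np.asarray(xp, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    np_ = np.asarray(np_, dtype=np.float64)
    tot = n + np_
    mu = np.divide(x + xp, tot, out=np.zeros_like(tot, dtype=np.float64),
                   where=tot > 0)
    l1 = betabin_loglik(x, n, mu, rho) + betabin_loglik(xp, np_, mu, rho)
    l0 = betabin_loglik(x, n, v, rho) + betabin_loglik(xp, np_, vp, rho)
    lr = np.maximum(2.0 * (np.asarray(l1) - np.asarray(l0)), 0.0)
    lr = np.where(np.asarray(mu) == 0, 0.0, lr)  # no alternate reads: p = 1
    p = stats.chi2.sf(lr, df=2)
    return p if p.ndim else float(p)


def bh_correct(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Calling pipeline
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Post-test filters, with the study's printed defaults."""

    min_total_coverage: int = 50   # strict: total reads must exceed this
    min_support: int = 5
    merge_distance: int = 5        # bases
    q_cutoff: float = 0.05
    germline_vaf: float = 0.3      # control VAF above this = germline heterozygote

    def __post_init__(self) -> None:
        if min(self.min_total_coverage, self.min_support,
               self.merge_distance) <= 0 or self.q_cutoff <= 0:
            raise ValueError("all filter thresholds must be positive")


@dataclass
class VariantCall:
    """A called subclonal variant (possibly a merged deletion span)."""

    sample: str
    chrom: str
    pos: int            # 1-based start
    end: int            # 1-based inclusive end (== pos for single-site calls)
    ref: str
    alt: str            # base, '-', or '<DEL>' for merged spans
    vaf: float
    p_value: float
    q_value: float
    support: int
    depth: int
    fwd_support: int = 0
    rev_support: int = 0
    merged_from: list["VariantCall"] = field(default_factory=list)


def _test_sample(counts: CountMatrix, sample_idx: int, model: ErrorModel
                 ) -> pd.DataFrame:
    """LRT over every non-reference allele at every covered position, then
    BH within the sample.  Returns a long table of tested cells."""
    P = len(counts.positions)
    ref_idx = counts.ref_index
    v = model.v_tested()
    n = counts.coverage[sample_idx, :, 0].astype(float)
    np_ = counts.coverage[sample_idx, :, 1].astype(float)
    rows = []
    for k, allele in enumerate(ALLELES):
        mask = (ref_idx != k) & (n + np_ > 0) & ~model.excluded
        if not mask.any():
            continue
        x = counts.counts[sample_idx, mask, k, 0].astype(float)
        xp = counts.counts[sample_idx, mask, k, 1].astype(float)
        pvals = lrt_site(x, xp, n[mask], np_[mask], v[mask, k, 0], v[mask, k, 1],
                         model.rho)
        idx = np.flatnonzero(mask)
        rows.append(pd.DataFrame({
            "pos_idx": idx, "allele": allele,
            "x": x, "xp": xp, "n": n[mask], "np": np_[mask], "p_value": pvals,
        }))
    if not rows:
        return pd.DataFrame(columns=["pos_idx", "allele", "x", "xp", "n", "np",
                                     "p_value", "q_value"])
    table = pd.concat(rows, ignore_index=True)
    table["q_value"] = bh_correct(table["p_value"].to_numpy())
    return table


def _merge_calls(calls: list[VariantCall], merge_distance: int) -> list[VariantCall]:
    """Transitively chain same-sample calls within ``merge_distance`` bases
    into one deletion-spanning record with the averaged VAF."""
    out: list[VariantCall] = []
    by_key: dict[tuple[str, str], list[VariantCall]] = {}
    for c in calls:
        by_key.setdefault((c.sample, c.chrom), []).append(c)
    for group in by_key.values():
        group.sort(key=lambda c: c.pos)
        chain: list[VariantCall] = []
        for c in group + [None]:
            if chain and (c is None or c.pos - chain[-1].pos > merge_distance):
                if len(chain) == 1:
                    out.append(chain[0])
                else:
                    out.append(VariantCall(
                        sample=chain[0].sample, chrom=chain[0].chrom,
                        pos=chain[0].pos, end=chain[-1].pos,
                        ref="".join(c.ref for c in chain), alt="<DEL>",
                        vaf=float(np.mean([c.vaf for c in chain])),
                        p_value=min(c.p_value for c in chain),
                        q_value=min(c.q_value for c in chain),
                        support=min(c.support for c in chain),
                        depth=min(c.depth for c in chain),
                        fwd_support=min(c.fwd_support for c in chain),
                        rev_support=min(c.rev_support for c in chain),
                        merged_from=list(chain)))
                chain = []
            if c is not None:
                chain.append(c)
    out.sort(key=lambda c: (c.sample, c.chrom, c.pos))
    return out


def call_variants(sample_counts: CountMatrix, control_counts: CountMatrix,
                  matched_control_id: str, model: ErrorModel,
                  config: FilterConfig | None = None,
                  sample: str | None = None) -> list[VariantCall]:
    """Call subclonal variants in one sample (or all samples) of a count matrix.

    Pipeline, in order: per-site per-alternate LRT against the background
    model → BH across all tested cells within the sample → q < cutoff →
    drop variants also present in the matched control (significant there,
    or at germline-level VAF) → require >50 total reads in both sample and
    matched control → require ≥5 supporting reads → merge calls within 5
    bases into a single deletion-spanning record with averaged VAF.
    """
    config = config or FilterConfig()
    ctrl_idx = control_counts.sample_index(matched_control_id)  # KeyError if absent
    if not sample_counts.positions[["chrom", "pos"]].equals(
            control_counts.positions[["chrom", "pos"]]):
        raise ValueError("sample and control matrices cover different positions")
    which = [sample] if sample is not None else sample_counts.samples

    # variants present in the matched control: significant there, or germline VAF
    ctrl_table = _test_sample(control_counts, ctrl_idx, model)
    ctrl_vaf = (ctrl_table["x"] + ctrl_table["xp"]) / (ctrl_table["n"] + ctrl_table["np"])
    in_control = set(map(tuple, ctrl_table.loc[
        (ctrl_table["q_value"] < config.q_cutoff) | (ctrl_vaf > config.germline_vaf),
        ["pos_idx", "allele"]].itertuples(index=False)))
    ctrl_total_cov = control_counts.coverage[ctrl_idx].sum(axis=1)

    all_calls: list[VariantCall] = []
    for samp in which:
        si = sample_counts.sample_index(samp)
        table = _test_sample(sample_counts, si, model)
        table = table[table["q_value"] < config.q_cutoff]
        calls: list[VariantCall] = []
        for row in table.itertuples(index=False):
            pi = int(row.pos_idx)
            if (pi, row.allele) in in_control:
                continue
            total_cov = row.n + row.np
            if total_cov <= config.min_total_coverage:
                continue
            if ctrl_total_cov[pi] <= config.min_total_coverage:
                continue
            support = int(row.x + row.xp)
            if support < config.min_support:
                continue
            posrec = sample_counts.positions.iloc[pi]
            calls.append(VariantCall(
                sample=samp, chrom=posrec["chrom"], pos=int(posrec["pos"]),
                end=int(posrec["pos"]), ref=posrec["ref"], alt=row.allele,
                vaf=float((row.x + row.xp) / total_cov),
                p_value=float(row.p_value), q_value=float(row.q_value),
                support=support, depth=int(total_cov),
                fwd_support=int(row.x), rev_support=int(row.xp)))
        all_calls.extend(_merge_calls(calls, config.merge_distance))
    return all_calls


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    cols = ["sample", "chrom", "pos", "end", "ref", "alt", "vaf",
            "p_value", "q_value", "support", "depth", "fwd_support", "rev_support"]
    return pd.DataFrame([{c: getattr(v, c) for c in cols} for v in calls],
                        columns=cols)


# ---------------------------------------------------------------------------
# Monte-Carlo spike-in benchmark
# ---------------------------------------------------------------------------

@dataclass
class SpikeBenchmarkResult:
    sensitivity: pd.DataFrame   # per spiked VAF: n_spiked, n_detected, sensitivity
    n_calls: int
    n_true: int
    n_false: int
    fdr: float
    fdr_se: float               # binomial Monte-Carlo standard error
    rho_fitted: float


def benchmark_spikein(config, seed: int = 0,
                      filter_config: FilterConfig | None = None
                      ) -> SpikeBenchmarkResult:
    """Sensitivity / false-discovery benchmark on simulated spiked mutations.

    Generates synthetic sample and control count matrices from ``config``
    (a :class:`epiclone.synthetic.SpikeConfig`), fits the error model on
    the controls, runs the full calling pipeline, and scores calls against
    the spike truth table.  A call matches a spike if it covers the spiked
    position with the spiked alternate allele (merged spans count if they
    cover the position).
    """
    from . import synthetic  # local import to avoid a cycle

    filter_config = filter_config or FilterConfig()
    sample_cm, control_cm, truth = synthetic.simulate_counts(config, seed=seed)
    model = fit_error_model(control_cm)
    calls = call_variants(sample_cm, control_cm,
                          matched_control_id=control_cm.samples[0], model=model,
                          config=filter_config)

    def _matches(call: VariantCall, t) -> bool:
        if call.sample != sample_cm.samples[t.sample]:
            return False
        pos = int(sample_cm.positions.iloc[t.site]["pos"])
        if call.alt == "<DEL>":
            return call.pos <= pos <= call.end
        return call.pos == pos and call.alt == t.alt

    detected = np.zeros(len(truth), dtype=bool)
    call_is_true = np.zeros(len(calls), dtype=bool)
    for i, t in enumerate(truth.itertuples(index=False)):
        for j, c in enumerate(calls):
            if _matches(c, t):
                detected[i] = True
                call_is_true[j] = True
    n_false = int((~call_is_true).sum())
    fdr = n_false / len(calls) if calls else 0.0
    fdr_se = float(np.sqrt(fdr * (1 - fdr) / len(calls))) if calls else 0.0
    sens = (truth.assign(detected=detected)
            .groupby("vaf")["detected"].agg(n_spiked="size", n_detected="sum"))
    sens["sensitivity"] = sens["n_detected"] / sens["n_spiked"]
    return SpikeBenchmarkResult(
        sensitivity=sens.reset_index(), n_calls=len(calls),
        n_true=int(call_is_true.sum()), n_false=n_false,
        fdr=fdr, fdr_se=fdr_se, rho_fitted=model.rho)
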