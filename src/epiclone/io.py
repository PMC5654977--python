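"""Tabular formats, reporting and the substitution-spectrum summaries.

All tables are tab-separated with documented headers.  Counts tables are
long format (one row per sample × position × strand), BED intervals are
0-based half-open, VCF output is minimal VCF 4.2.  Malformed rows raise
:class:`TableFormatError` naming the offending line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clonestats
from .caller import ALLELES, CountMatrix, VariantCall

COUNTS_COLUMNS = ["sample", "chrom", "pos", "ref", "strand",
                  "A", "C", "G", "T", "DEL", "depth"]
MUTATION_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "vaf", "consequence"]
CONSEQUENCE_CLASSES = ("synonymous", "nonsynonymous", "frameshift",
                       "splicing", "other")
PROTEIN_ALTERING = ("nonsynonymous", "frameshift", "splicing")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: 6 collapsed substitution classes, pyrimidine-reference convention.
COLLAPSED_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


class TableFormatError(ValueError):
    """Malformed table row; the message names the 1-based file line."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing} (header line 1)")


def _check_rows(df: pd.DataFrame, ok: pd.Series, path, what: str) -> None:
    if ok.all():
        return
    line = int(df.index[~ok][0]) + 2  # +1 header, +1 one-based
    raise TableFormatError(f"{path}: line {line}: {what}")


# ---------------------------------------------------------------------------
# Counts tables
# ---------------------------------------------------------------------------

def write_counts_table(cm: CountMatrix, path) -> None:
    rows = []
    for si, sample in enumerate(cm.samples):
        for pi, rec in enumerate(cm.positions.itertuples(index=False)):
            for strand, symbol in enumerate("+-"):
                c = cm.counts[si, pi, :, strand]
                rows.append((sample, rec.chrom, rec.pos, rec.ref, symbol,
                             *c, cm.coverage[si, pi, strand]))
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts_table(path) -> CountMatrix:
    """Read a long-format strand-specific counts table into a CountMatrix."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, COUNTS_COLUMNS, path)
    _check_rows(df, df["strand"].isin(["+", "-"]), path, "strand must be + or -")
    _check_rows(df, df["ref"].isin(ALLELES[:4]), path, "ref must be A/C/G/T")
    for col in ("A", "C", "G", "T", "DEL", "depth", "pos"):
        _check_rows(df, pd.to_numeric(df[col], errors="coerce").notna(),
                    path, f"non-numeric {col}")
    _check_rows(df, df[list("ACGT") + ["DEL"]].sum(axis=1) <= df["depth"],
                path, "allele counts exceed depth")
    samples = list(dict.fromkeys(df["sample"]))
    positions = (df[["chrom", "pos", "ref"]].drop_duplicates()
                 .sort_values(["chrom", "pos"]).reset_index(drop=True))
    s_idx = {s: i for i, s in enumerate(samples)}
    p_idx = {(c, p): i for i, (c, p) in
             enumerate(zip(positions["chrom"], positions["pos"]))}
    counts = np.zeros((len(samples), len(positions), len(ALLELES), 2), np.int64)
    coverage = np.zeros((len(samples), len(positions), 2), np.int64)
    si = df["sample"].map(s_idx).to_numpy()
    pi = pd.Series(zip(df["chrom"], df["pos"])).map(p_idx).to_numpy()
    st = (df["strand"] == "-").astype(int).to_numpy()
    for k, col in enumerate(list("ACGT") + ["DEL"]):
        counts[si, pi, k, st] = df[col].to_numpy()
    coverage[si, pi, st] = df["depth"].to_numpy()
    return CountMatrix(samples=samples, positions=positions,
                       counts=counts, coverage=coverage)


# ---------------------------------------------------------------------------
# Clone and mutation tables
# ---------------------------------------------------------------------------

def read_clone_table(path) -> pd.DataFrame:
    """Clone-size table: columns clone_id and cells and/or vaf."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["clone_id"], path)
    if "cells" not in df.columns and "vaf" not in df.columns:
        raise TableFormatError(f"{path}: need a 'cells' or 'vaf' column")
    for col in ("cells", "vaf"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            _check_rows(df, vals.notna(), path, f"non-numeric {col}")
            _check_rows(df, vals > 0, path, f"non-positive {col}")
    return df


def write_clone_trajectory(result, path) -> None:
    """Write per-checkpoint clone sizes from a lattice RunResult.

    Columns: checkpoint_day, clone_label, parent_label, mutation_class,
    cells, vaf.
    """
    from .lattice import MUTATION_CLASS_NAMES, clone_sizes

    tree = result.tree
    rows = []
    # final checkpoint carries full lineage info from the surviving tree
    for day, sample in sorted(result.samples.items()):
        if day == max(result.samples):
            totals = tree.recursive_sizes(result.state)
            occ = result.state.n_occupied
            for row in range(len(tree)):
                if totals[row] == 0 and row != 0:
                    continue
                rows.append((day, int(tree.ids[row]), int(tree.parent[row]),
                             MUTATION_CLASS_NAMES[int(tree.mutation_class[row])],
                             int(totals[row]), totals[row] / occ / 2.0))
        else:
            for size, vaf in zip(sample.sizes, sample.vaf):
                rows.append((day, -1, -1, "unknown", int(size), vaf))
    pd.DataFrame(rows, columns=["checkpoint_day", "clone_label", "parent_label",
                                "mutation_class", "cells", "vaf"]
                 ).to_csv(path, sep="\t", index=False)


def read_mutation_table(path) -> pd.DataFrame:
    """Mutation table: sample, chrom, pos, ref, alt, vaf, consequence[, context]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, MUTATION_COLUMNS, path)
    vaf = pd.to_numeric(df["vaf"], errors="coerce")
    _check_rows(df, vaf.notna() & (vaf > 0) & (vaf <= 1), path,
                "vaf must lie in (0, 1]")
    _check_rows(df, df["consequence"].isin(CONSEQUENCE_CLASSES), path,
                f"consequence must be one of {CONSEQUENCE_CLASSES}")
    return df


def write_mutation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED and VCF
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read capture targets (BED, 0-based half-open) into chrom/start/end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    for col in ("start", "end"):
        _check_rows(df, pd.to_numeric(df[col], errors="coerce").notna(),
                    path, f"non-numeric {col}")
    _check_rows(df, df["end"] > df["start"], path, "end must exceed start")
    return df


def bed_covers(bed: pd.DataFrame, chrom: str, pos: int) -> bool:
    """Whether a 1-based position falls in the 0-based half-open targets."""
    rows = bed[bed["chrom"] == chrom]
    return bool(((rows["start"] < pos) & (pos <= rows["end"])).any())


def write_vcf(calls: list[VariantCall], path, reference: str = "synthetic") -> None:
    """Write calls as minimal VCF 4.2 (INFO: VAF, SUPPORT, QVAL; merged
    deletion spans use the symbolic ALT <DEL> with an END tag)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={reference}",
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">',
        '##INFO=<ID=QVAL,Number=1,Type=Float,Description="BH-adjusted p-value">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of deletion span">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample of origin">',
        '##ALT=<ID=DEL,Description="Merged deletion spanning nearby calls">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        if c.alt == "<DEL>":
            ref, alt = c.ref[0], "<DEL>"
            extra = f";END={c.end}"
        elif c.alt == "-":
            ref, alt = c.ref, "<DEL>"
            extra = f";END={c.pos}"
        else:
            ref, alt, extra = c.ref, c.alt, ""
        info = (f"VAF={c.vaf:.6g};SUPPORT={c.support};QVAL={c.q_value:.6g}"
                f";SAMPLE={c.sample}{extra}")
        lines.append(f"{c.chrom}\t{c.pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Substitution spectra
# ---------------------------------------------------------------------------

def spectrum_summary(mutations: pd.DataFrame) -> dict:
    """Tabulate substitution classes from a mutation table.

    Returns a dict with '12_class' counts on the coding strand, '6_class'
    counts collapsed to the pyrimidine-reference convention, and, when a
    context column is present, '96_context' counts keyed by
    (collapsed class, pyrimidine-strand trinucleotide).  Totals over each
    classification equal the number of substitution rows.
    """
    subs = mutations[(mutations["ref"].str.len() == 1) & (mutations["alt"].str.len() == 1)
                     & (mutations["alt"] != "-")]
    bad = ~(subs["ref"].isin(list("ACGT")) & subs["alt"].isin(list("ACGT")))
    if bad.any():
        raise ValueError(f"unknown base characters in rows {list(subs.index[bad][:5])}")
    twelve = {f"{r}>{a}": 0 for r in "ACGT" for a in "ACGT" if r != a}
    six = {c: 0 for c in COLLAPSED_CLASSES}
    for r, a in zip(subs["ref"], subs["alt"]):
        twelve[f"{r}>{a}"] += 1
        if r in "CT":
            six[f"{r}>{a}"] += 1
        else:
            six[f"{_COMPLEMENT[r]}>{_COMPLEMENT[a]}"] += 1
    out = {"12_class": twelve, "6_class": six, "n_substitutions": int(len(subs))}
    if "context" in subs.columns and subs["context"].notna().all() and len(subs):
        ctx_counts: dict[tuple[str, str], int] = {}
        for r, a, ctx in zip(subs["ref"], subs["alt"], subs["context"]):
            if len(ctx) != 3 or any(b not in "ACGT" for b in ctx) or ctx[1] != r:
                raise ValueError(f"malformed trinucleotide context {ctx!r}")
            if r in "CT":
                key = (f"{r}>{a}", ctx)
            else:
                rc = "".join(_COMPLEMENT[b] for b in reversed(ctx))
                key = (f"{_COMPLEMENT[r]}>{_COMPLEMENT[a]}", rc)
            ctx_counts[key] = ctx_counts.get(key, 0) + 1
        out["96_context"] = ctx_counts
    return out


def stratified_distributions(mutations: pd.DataFrame) -> dict:
    """Split clone sizes (VAFs) into synonymous vs protein-altering strata.

    Returns, per non-empty stratum, the VAF array and the empirical first
    incomplete moment curve; empty strata are listed under 'skipped'.
    """
    strata = {
        "synonymous": mutations[mutations["consequence"] == "synonymous"],
        "protein_altering": mutations[mutations["consequence"].isin(PROTEIN_ALTERING)],
    }
    out: dict = {"skipped": []}
    for name, rows in strata.items():
        if rows.empty:
            out["skipped"].append(name)
            continue
        vafs = rows["vaf"].to_numpy(dtype=float)
        n, moment = clonestats.first_incomplete_moment(vafs)
        out[name] = {"vaf": vafs, "curve_n": n, "curve_moment": moment}
    return out
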