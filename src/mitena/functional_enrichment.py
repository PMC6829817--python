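"""Functional over-representation analysis of miRNA target genes.

The targets of an enriched miRNA are tested against user-supplied gene-set
collections in GMT format (the standard carrier for KEGG / Reactome /
WikiPathways-style annotation).  The statistic is the same hypergeometric
upper tail used for the miRNA-target test, applied to the category urn:
M = background size, K = category size within the background, N = input
targets within the background, X = hits.

The reported *gene ratio* is hits / category size (the fraction of a
category's genes recovered among the targets).  Note that several popular
tools instead report hits / input size; that convention is available via
``gene_ratio="input"`` and the output header names the convention in use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mitena.enrichment import adjust_fdr, hypergeom_pvalue


class GMTFormatError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets plus their union universe (default ORA background)."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()

    def __len__(self) -> int:
        return len(self.sets)


def load_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then member genes.

    Genes are upper-cased; duplicates within a line count once.  A line with
    fewer than three tab-separated fields raises :class:`GMTFormatError`
    naming the line number; an empty file raises it too.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}")
            name = fields[0].strip()
            genes = {g.strip().upper() for g in fields[2:] if g.strip()}
            if not genes:
                raise GMTFormatError(f"{path}:{lineno}: category {name!r} has no member genes")
            sets[name] = genes
    if not sets:
        raise GMTFormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets)


ORA_COLUMNS = ["category", "hits", "category_size", "input_size", "gene_ratio", "p_value", "fdr", "overlap"]


def ora(target_genes, collection: GeneSetCollection, background=None,
        gene_ratio: str = "category") -> pd.DataFrame:
    """Hypergeometric ORA of a target-gene set against every category.

    ``background`` defaults to the collection's union universe.  Categories
    and targets are intersected with the background before counting; target
    genes entirely disjoint from the background raise ``ValueError`` listing
    the unmatched symbols.  Returns one row per category, BH-adjusted,
    sorted by p-value then category name.  ``gene_ratio`` selects the
    denominator: ``"category"`` (hits / category size) or ``"input"``
    (hits / matched input size); the chosen convention is recorded in
    ``df.attrs["gene_ratio_convention"]``.
    """
    if gene_ratio not in ("category", "input"):
        raise ValueError(f"gene_ratio must be 'category' or 'input', got {gene_ratio!r}")
    targets = {str(g).strip().upper() for g in target_genes if str(g).strip()}
    if not targets:
        raise ValueError("target gene set is empty")
    bg = set(background) if background is not None else set(collection.universe)
    bg = {str(g).strip().upper() for g in bg}
    matched = targets & bg
    if not matched:
        raise ValueError(
            "no target genes found in the background; unmatched: "
            + ", ".join(sorted(targets)[:20])
        )
    M = len(bg)
    N = len(matched)
    rows = []
    for name, members in collection.sets.items():
        cat = members & bg
        K = len(cat)
        hit = sorted(cat & matched)
        X = len(hit)
        p = hypergeom_pvalue(M, K, N, X) if K > 0 else 1.0
        denom = K if gene_ratio == "category" else N
        rows.append((name, X, K, N, (X / denom) if denom else 0.0, p, hit))
    df = pd.DataFrame(rows, columns=["category", "hits", "category_size", "input_size",
                                     "gene_ratio", "p_value", "overlap"])
    df["fdr"] = adjust_fdr(df["p_value"].to_numpy())
    df = df[ORA_COLUMNS].sort_values(["p_value", "category"], kind="mergesort").reset_index(drop=True)
    df.attrs["gene_ratio_convention"] = (
        "hits/category_size" if gene_ratio == "category" else "hits/input_size"
    )
    return df


def write_ora(df: pd.DataFrame, path) -> None:
    """TSV output; a header comment names the gene-ratio convention."""
    out = df.copy()
    out["overlap"] = out["overlap"].map(";".join)
    with open(path, "w") as fh:
        conv = df.attrs.get("gene_ratio_convention", "hits/category_size")
        fh.write(f"# gene_ratio = {conv}\n")
        out.to_csv(fh, sep="\t", index=False)


def plot_ora_dotplot(results: dict[str, pd.DataFrame], path, top: int = 10) -> None:
    """Dot plot of categories (rows) × miRNAs (columns).

    Dot size encodes gene ratio, colour encodes FDR; ``results`` maps a
    miRNA identifier to its ORA table.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats: list[str] = []
    for df in results.values():
        for c in df.nsmallest(top, "p_value")["category"]:
            if c not in cats:
                cats.append(c)
    mirnas = list(results)
    fig, ax = plt.subplots(figsize=(2 + 0.9 * len(mirnas), 1 + 0.35 * len(cats)))
    xs, ys, sizes, colours = [], [], [], []
    for j, m in enumerate(mirnas):
        df = results[m].set_index("category")
        for i, c in enumerate(cats):
            if c in df.index:
                xs.append(j)
                ys.append(i)
                sizes.append(40 + 400 * float(df.loc[c, "gene_ratio"]))
                colours.append(float(df.loc[c, "fdr"]))
    sc = ax.scatter(xs, ys, s=sizes, c=colours, cmap="viridis_r", vmin=0, vmax=1)
    ax.set_xticks(range(len(mirnas)), mirnas, rotation=45, ha="right")
    ax.set_yticks(range(len(cats)), cats)
    ax.invert_yaxis()
    fig.colorbar(sc, ax=ax, label="FDR")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
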