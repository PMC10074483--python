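"""Relative qPCR quantification (2^-ddCt) with reference-gene normalization.

Input is a long-format Ct table (one row per well): sample_id, group, gene,
replicate, ct. Replicate wells are averaged per (sample, gene); the
reference summary is the arithmetic mean of the reference-gene Cts — on the
Ct (log2) scale this equals the log of the geometric mean of the reference
quantities; dCt = Ct_target - reference summary; ddCt subtracts the
control-group mean dCt per gene; fold change = efficiency^(-ddCt) with
efficiency fixed at 2 by default.

A matching synthetic Ct generator emulates the LPS induction experiment:
strongly induced pro-inflammatory transcripts (Il1b, Tnf, Cxcl1), a modestly
induced antagonist (Il1rn), and two stable reference genes (Actb, s2Vb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CT_COLUMNS",
    "FoldChangeResult",
    "fold_changes",
    "simulate_ct_table",
    "DEFAULT_REF_GENES",
    "DEFAULT_LPS_EFFECTS",
]

CT_COLUMNS = ("sample_id", "group", "gene", "replicate", "ct")
DEFAULT_REF_GENES = ("Actb", "s2Vb")
QPCR_GROUPS = ("aCSF", "LPS_30min_washout", "LPS_60min_washout")

#: log2 fold inductions per gene and group used by the synthetic generator.
#: The magnitudes are invented (the underlying measurements are figure-only);
#: they reproduce the induction *pattern*: strong Il1b/Tnf/Cxcl1, minor Il1rn.
DEFAULT_LPS_EFFECTS: dict[str, dict[str, float]] = {
    "Il1b": {"LPS_30min_washout": 5.0, "LPS_60min_washout": 4.5},
    "Il1rn": {"LPS_30min_washout": 1.5, "LPS_60min_washout": 2.0},
    "Tnf": {"LPS_30min_washout": 4.0, "LPS_60min_washout": 4.0},
    "Cxcl1": {"LPS_30min_washout": 4.5, "LPS_60min_washout": 4.0},
}

_BASELINE_CT = {
    "Actb": 17.5,
    "s2Vb": 20.0,
    "Il1b": 26.0,
    "Il1rn": 27.0,
    "Tnf": 28.0,
    "Cxcl1": 27.5,
}


@dataclass
class FoldChangeResult:
    per_sample: pd.DataFrame  # sample_id, group, gene, dct, ddct, fold
    group_summary: pd.DataFrame  # group, gene, n, mean_fold, sem_fold
    ratios: pd.DataFrame  # sample_id, group, ratio columns per requested pair


def _validate(table: pd.DataFrame, ref_genes: tuple[str, ...]) -> None:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if ((table["ct"] <= 0) | (table["ct"] >= 45)).any():
        raise ValueError("Ct values must lie in (0, 45)")
    genes_by_sample = table.groupby("sample_id")["gene"].apply(set)
    for ref in ref_genes:
        lacking = [s for s, genes in genes_by_sample.items() if ref not in genes]
        if lacking:
            raise ValueError(f"reference gene {ref!r} missing for samples {lacking}")


def fold_changes(
    table: pd.DataFrame,
    control_group: str = "aCSF",
    ref_genes: tuple[str, ...] = DEFAULT_REF_GENES,
    efficiency: float = 2.0,
    ratio_pairs: tuple[tuple[str, str], ...] = (("Il1b", "Il1rn"),),
) -> FoldChangeResult:
    """Reference-normalized fold changes relative to the control-group mean."""
    _validate(table, ref_genes)
    if control_group not in set(table["group"]):
        raise ValueError(f"control group {control_group!r} absent from table")

    mean_ct = (
        table.groupby(["sample_id", "group", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    ref = (
        mean_ct[mean_ct["gene"].isin(ref_genes)]
        .groupby("sample_id")["ct"]
        .mean()
        .rename("ref_ct")
    )
    targets = mean_ct[~mean_ct["gene"].isin(ref_genes)].merge(ref, on="sample_id")
    targets["dct"] = targets["ct"] - targets["ref_ct"]

    control_mean = (
        targets[targets["group"] == control_group].groupby("gene")["dct"].mean()
    )
    unknown = set(targets["gene"]) - set(control_mean.index)
    if unknown:
        raise ValueError(f"genes absent from control group: {sorted(unknown)}")
    targets["ddct"] = targets["dct"] - targets["gene"].map(control_mean)
    targets["fold"] = efficiency ** (-targets["ddct"])

    per_sample = targets[["sample_id", "group", "gene", "dct", "ddct", "fold"]]
    group_summary = (
        per_sample.groupby(["group", "gene"], sort=False)["fold"]
        .agg(
            n="count",
            mean_fold="mean",
            sem_fold=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
        )
        .reset_index()
    )

    wide = per_sample.pivot_table(index=["sample_id", "group"], columns="gene", values="fold")
    ratio_rows = wide.reset_index()[["sample_id", "group"]].copy()
    for num, den in ratio_pairs:
        if num in wide.columns and den in wide.columns:
            ratio_rows[f"{num}/{den}"] = (wide[num] / wide[den]).to_numpy()
    return FoldChangeResult(per_sample, group_summary, ratio_rows)


def simulate_ct_table(
    effects: dict[str, dict[str, float]] | None = None,
    noise_sd_ct: float = 0.3,
    n_per_group: int = 8,
    seed: int = 0,
    groups: tuple[str, ...] = QPCR_GROUPS,
    control_group: str = "aCSF",
    n_replicates: int = 3,
    baseline_ct: dict[str, float] | None = None,
    ref_genes: tuple[str, ...] = DEFAULT_REF_GENES,
) -> pd.DataFrame:
    """Synthetic triplicate Ct table: Ct = baseline - log2fold + noise."""
    if noise_sd_ct < 0:
        raise ValueError("noise_sd_ct must be non-negative")
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    effects = DEFAULT_LPS_EFFECTS if effects is None else effects
    baseline_ct = dict(_BASELINE_CT) if baseline_ct is None else baseline_ct
    genes = list(ref_genes) + [g for g in effects if g not in ref_genes]
    for g in genes:
        if g not in baseline_ct:
            raise ValueError(f"no baseline Ct for gene {g!r}")
    rng = np.random.Generator(np.random.PCG64(seed))
    rows = []
    for group in groups:
        for i in range(n_per_group):
            sample = f"{group}_s{i}"
            for gene in genes:
                log2fold = 0.0
                if group != control_group and gene in effects:
                    log2fold = effects[gene].get(group, 0.0)
                base = baseline_ct[gene] - log2fold
                for rep in range(n_replicates):
                    noise = rng.normal(0.0, noise_sd_ct) if noise_sd_ct > 0 else 0.0
                    rows.append(
                        {
                            "sample_id": sample,
                            "group": group,
                            "gene": gene,
                            "replicate": rep,
                            "ct": base + noise,
                        }
                    )
    return pd.DataFrame(rows, columns=list(CT_COLUMNS))
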