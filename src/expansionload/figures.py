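"""Figure analogs of the study's simulation summaries.

Consumes the tidy trajectory TSVs written by the ``simulate`` command (one
file per replicate, columns keyed by replicate/sigma/generation/deme) and
draws: the expansion-time distribution, end-state diversity and fitness by
deme, shift-aligned trajectories of heterozygosity / lethal counts /
fitness-change rate, and the binned realized DFE with 0.05/0.95 replicate
quantiles.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["load_trajectories", "shift_aligned", "make_figures"]


def load_trajectories(trajectory_dir) -> pd.DataFrame:
    files = sorted(Path(trajectory_dir).glob("trajectory_*.tsv"))
    if not files:
        raise FileNotFoundError(f"no trajectory_*.tsv files in {trajectory_dir}")
    frames = [pd.read_csv(f, sep="\t", comment="#") for f in files]
    df = pd.concat(frames, ignore_index=True)
    required = {"replicate", "sigma", "generation", "deme", "mean_fitness"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory files lack columns: {sorted(missing)}")
    return df


def shift_aligned(df: pd.DataFrame, shift_deme: int) -> pd.DataFrame:
    """Re-zero each replicate's time axis at the generation its expansion
    front first reached the mating-shift deme (replicates vary in when that
    happens, so absolute generations are not comparable)."""
    out = []
    for (sigma, rep), sub in df.groupby(["sigma", "replicate"]):
        arrived = sub[sub["deme"] >= shift_deme]
        if arrived.empty:
            continue
        t0 = arrived["generation"].min()
        s = sub.copy()
        s["t_rel"] = s["generation"] - t0
        out.append(s)
    return pd.concat(out, ignore_index=True) if out else df.assign(t_rel=np.nan)


def _expansion_times(df: pd.DataFrame, k_deme: int) -> pd.DataFrame:
    rows = []
    last = df["deme"].max()
    for (sigma, rep), sub in df.groupby(["sigma", "replicate"]):
        start = sub["generation"].min()
        crossed = sub[(sub["deme"] == last) & (sub["census"] >= k_deme)]
        if crossed.empty:
            continue
        rows.append({"sigma": sigma, "replicate": rep, "expansion_time": crossed["generation"].min() - start})
    return pd.DataFrame(rows)


def make_figures(trajectory_dir, out_dir, shift_deme: int = 25, k_deme: int = 200) -> list[Path]:
    df = load_trajectories(trajectory_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    # expansion-time distribution by selfing rate
    et = _expansion_times(df, k_deme)
    fig, ax = plt.subplots(figsize=(5, 4))
    if not et.empty:
        groups = [g["expansion_time"].to_numpy() for _, g in et.groupby("sigma")]
        ax.boxplot(groups, tick_labels=[f"sigma={s}" for s, _ in et.groupby("sigma")])
    ax.set_ylabel("generations to cross the landscape")
    p = out_dir / "expansion_time.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # end-state pi and fitness by deme
    t_end = df.groupby(["sigma", "replicate"])["generation"].transform("max")
    end = df[df["generation"] == t_end]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for sigma, sub in end.groupby("sigma"):
        by = sub.groupby("deme")[["pi_neutral", "mean_fitness"]].mean()
        axes[0].plot(by.index, by["pi_neutral"], marker="o", label=f"sigma={sigma}")
        axes[1].plot(by.index, by["mean_fitness"], marker="o", label=f"sigma={sigma}")
    axes[0].set_xlabel("deme")
    axes[0].set_ylabel("neutral pi")
    axes[1].set_xlabel("deme")
    axes[1].set_ylabel("mean fitness")
    axes[0].legend(fontsize=7)
    p = out_dir / "end_state_by_deme.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # shift-aligned trajectories at the front
    al = shift_aligned(df, shift_deme)
    if "t_rel" in al.columns:
        front = al.loc[al.groupby(["sigma", "replicate", "generation"])["deme"].idxmax()]
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for sigma, sub in front.groupby("sigma"):
            m = sub.groupby("t_rel")[["H_obs", "mean_lethal_alleles"]].mean()
            axes[0].plot(m.index, m["H_obs"], label=f"sigma={sigma}")
            axes[1].plot(m.index, m["mean_lethal_alleles"], label=f"sigma={sigma}")
        for ax, lab in zip(axes, ("observed heterozygosity", "lethal alleles per individual")):
            ax.axvline(0, ls="--", c="k", lw=0.8)
            ax.set_xlabel("generations since mating shift")
            ax.set_ylabel(lab)
        axes[0].legend(fontsize=7)
        p = out_dir / "front_trajectories.png"
        fig.tight_layout()
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written


def dfe_bin_figure(bin_table: pd.DataFrame, out_path) -> Path:
    """Barplot of realized DFE-bin proportions with 0.05/0.95 replicate
    quantiles; expects tidy columns (sigma, deme_role, replicate, bin,
    proportion)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    groups = list(bin_table.groupby(["sigma", "deme_role"]))
    width = 0.8 / max(len(groups), 1)
    bins = ["weak", "mid", "strong", "lethal"]
    x = np.arange(len(bins))
    for k, ((sigma, role), sub) in enumerate(groups):
        agg = sub.groupby("bin")["proportion"]
        mean = agg.mean().reindex(bins)
        lo = agg.quantile(0.05).reindex(bins)
        hi = agg.quantile(0.95).reindex(bins)
        ax.bar(
            x + k * width,
            mean,
            width=width,
            yerr=np.vstack([(mean - lo).to_numpy(), (hi - mean).to_numpy()]),
            label=f"{role}, sigma={sigma}",
            capsize=2,
        )
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(bins)
    ax.set_ylabel("proportion of segregating selected sites")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
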