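"""Aggregation of per-focus records into per-condition summary statistics.

The experimental readouts are descriptive: foci per cell, the three-zone
breakdown of mRNA foci against the nucleoid, mRNA–plasmid pairing
fractions, and the fraction of cells with dispersed (non-focal) signal.
Uncertainty is quantified by a seeded nonparametric bootstrap that
resamples *cells* with replacement — cells, not foci, are the independent
units of the experimental design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ZONE_ORDER = ("NUCLEOID_OVERLAP", "PERIPHERAL", "NUCLEOID_FREE")
PAIR_ORDER = ("COLOCALIZED", "ADJACENT", "SEPARATE")


@dataclass
class SummaryStats:
    """Summary of one group (condition × channel)."""

    label: str
    channel: str
    n_cells: int
    n_foci: int
    foci_per_cell: float
    foci_per_cell_ci: tuple
    zone_fractions: dict          # zone -> fraction (sums to 1 over foci w/ zones)
    zone_cis: dict                # zone -> (lo, hi)
    pairing_fractions: dict
    dispersed_cell_fraction: float | None = None
    per_cell_counts: np.ndarray = field(default=None, repr=False)

    @property
    def counts_available(self) -> bool:
        return self.per_cell_counts is not None and len(self.per_cell_counts) > 0

    def to_rows(self) -> list[dict]:
        rows = [
            {"group": self.label, "channel": self.channel, "statistic": "n_cells", "value": self.n_cells},
            {"group": self.label, "channel": self.channel, "statistic": "n_foci", "value": self.n_foci},
            {
                "group": self.label,
                "channel": self.channel,
                "statistic": "foci_per_cell",
                "value": self.foci_per_cell,
                "ci_lo": self.foci_per_cell_ci[0],
                "ci_hi": self.foci_per_cell_ci[1],
            },
        ]
        for z in ZONE_ORDER:
            if z in self.zone_fractions:
                lo, hi = self.zone_cis.get(z, (np.nan, np.nan))
                rows.append(
                    {
                        "group": self.label,
                        "channel": self.channel,
                        "statistic": f"zone_fraction[{z}]",
                        "value": self.zone_fractions[z],
                        "ci_lo": lo,
                        "ci_hi": hi,
                    }
                )
        for p, v in self.pairing_fractions.items():
            rows.append(
                {"group": self.label, "channel": self.channel, "statistic": f"pairing_fraction[{p}]", "value": v}
            )
        if self.dispersed_cell_fraction is not None:
            rows.append(
                {
                    "group": self.label,
                    "channel": self.channel,
                    "statistic": "dispersed_cell_fraction",
                    "value": self.dispersed_cell_fraction,
                }
            )
        return rows


def _bootstrap_ci(per_cell_values, stat, n_boot, rng, alpha=0.05):
    n = len(per_cell_values)
    if n == 0:
        return (np.nan, np.nan)
    idx = rng.integers(0, n, size=(n_boot, n))
    reps = np.array([stat(per_cell_values[i]) for i in idx])
    return (float(np.quantile(reps, alpha / 2)), float(np.quantile(reps, 1 - alpha / 2)))


def summarize(
    records: pd.DataFrame,
    group_keys: list[str] | None = None,
    cells: pd.DataFrame | None = None,
    dispersion: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    denominator: str = "all_cells",
) -> list[SummaryStats]:
    """Aggregate a per-focus record table into grouped summary statistics.

    ``records`` needs columns cell_id, channel and (for red foci) zone and
    pair_label; extra grouping columns named in ``group_keys`` are carried
    through.  ``cells`` (cell_id plus the group keys) supplies the
    denominator when ``denominator="all_cells"``, so cells without foci
    count; with ``denominator="cells_with_foci"`` only cells contributing
    at least one focus do.  ``dispersion`` (cell_id, channel, pattern)
    yields the dispersed-cell fraction.  Bootstrap CIs (95%) resample
    cells with replacement, ``n_boot`` replicates, seeded.
    """
    group_keys = list(group_keys or [])
    for col in ("cell_id", "channel"):
        if col not in records.columns:
            raise ValueError(f"records table lacks required column {col!r}")

    rng_root = np.random.default_rng(seed)
    out = []
    grouping = group_keys + ["channel"]
    key_iter = (
        records.groupby(grouping, sort=True, dropna=False)
        if len(records)
        else []
    )
    for keys, grp in key_iter:
        keys = keys if isinstance(keys, tuple) else (keys,)
        channel = keys[-1]
        label = "/".join(str(k) for k in keys[:-1]) or "all"

        if cells is not None and denominator == "all_cells":
            cell_sel = cells
            for k, v in zip(group_keys, keys[:-1]):
                if k in cells.columns:
                    cell_sel = cell_sel[cell_sel[k] == v]
            cell_ids = np.sort(cell_sel["cell_id"].unique())
        else:
            cell_ids = np.sort(grp["cell_id"].unique())
        n_cells = len(cell_ids)
        if n_cells == 0:
            warnings.warn(f"group {label}/{channel}: no cells, omitted")
            continue

        counts = grp.groupby("cell_id").size()
        per_cell = np.array([counts.get(c, 0) for c in cell_ids], dtype=float)
        n_foci = int(per_cell.sum())
        rng = np.random.default_rng(rng_root.integers(2**31 - 1))
        fpc_ci = _bootstrap_ci(per_cell, np.mean, n_boot, rng)

        zone_fr, zone_ci = {}, {}
        if "zone" in grp.columns and grp["zone"].notna().any():
            zoned = grp[grp["zone"].notna()]
            cell_zone_counts = {
                c: np.array(
                    [ (zoned[(zoned.cell_id == c)].zone == z).sum() for z in ZONE_ORDER ],
                    dtype=float,
                )
                for c in cell_ids
            }
            tot = sum(cell_zone_counts.values())
            if tot.sum() > 0:
                fr = tot / tot.sum()
                zone_fr = dict(zip(ZONE_ORDER, fr))
                mat = np.array([cell_zone_counts[c] for c in cell_ids])
                for zi, z in enumerate(ZONE_ORDER):
                    def frac(rows, zi=zi):
                        s = rows.sum(axis=0)
                        return s[zi] / s.sum() if s.sum() > 0 else np.nan
                    idx = rng.integers(0, n_cells, size=(n_boot, n_cells))
                    reps = np.array([frac(mat[i]) for i in idx])
                    reps = reps[~np.isnan(reps)]
                    zone_ci[z] = (
                        (float(np.quantile(reps, 0.025)), float(np.quantile(reps, 0.975)))
                        if len(reps)
                        else (np.nan, np.nan)
                    )

        pair_fr = {}
        if "pair_label" in grp.columns and grp["pair_label"].notna().any():
            paired = grp[grp["pair_label"].notna()]
            vc = paired["pair_label"].value_counts(normalize=True)
            pair_fr = {p: float(vc.get(p, 0.0)) for p in PAIR_ORDER}

        disp_frac = None
        if dispersion is not None and len(dispersion):
            d = dispersion[
                (dispersion["channel"] == channel) & dispersion["cell_id"].isin(cell_ids)
            ]
            with_signal = d[d["pattern"] != "NO_SIGNAL"]
            if len(with_signal):
                disp_frac = float((with_signal["pattern"] == "DISPERSED").mean())

        out.append(
            SummaryStats(
                label=label,
                channel=channel,
                n_cells=n_cells,
                n_foci=n_foci,
                foci_per_cell=float(per_cell.mean()),
                foci_per_cell_ci=fpc_ci,
                zone_fractions=zone_fr,
                zone_cis=zone_ci,
                pairing_fractions=pair_fr,
                dispersed_cell_fraction=disp_frac,
                per_cell_counts=per_cell,
            )
        )
    return out


def summary_table(stats: list[SummaryStats]) -> pd.DataFrame:
    """Long-format table: one row per group × statistic."""
    rows = []
    for s in stats:
        rows.extend(s.to_rows())
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    label_a: str
    label_b: str
    channel: str
    mean_a: float
    mean_b: float
    pct_change: float          # NaN when the baseline mean is zero
    diff_ci: tuple             # bootstrap 95% CI of (mean_b - mean_a)


def compare_conditions(a: SummaryStats, b: SummaryStats, n_boot: int = 1000, seed: int = 0) -> ComparisonReport:
    """Relative change in foci per cell between two groups (b versus a)."""
    if a.channel != b.channel:
        raise ValueError("can only compare groups of the same channel")
    rng = np.random.default_rng(seed)
    if a.counts_available and b.counts_available:
        na, nb = len(a.per_cell_counts), len(b.per_cell_counts)
        ia = rng.integers(0, na, size=(n_boot, na))
        ib = rng.integers(0, nb, size=(n_boot, nb))
        diffs = a.per_cell_counts[ia].mean(axis=1) * -1 + b.per_cell_counts[ib].mean(axis=1)
        ci = (float(np.quantile(diffs, 0.025)), float(np.quantile(diffs, 0.975)))
    else:
        ci = (np.nan, np.nan)
    if a.foci_per_cell == 0:
        pct = float("nan")
    else:
        pct = 100.0 * (b.foci_per_cell - a.foci_per_cell) / a.foci_per_cell
    return ComparisonReport(
        label_a=a.label,
        label_b=b.label,
        channel=a.channel,
        mean_a=a.foci_per_cell,
        mean_b=b.foci_per_cell,
        pct_change=pct,
        diff_ci=ci,
    )


# ---------------------------------------------------------------------------
# probe manifests

VALID_BASES = set("ACGTU")


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    sequence: str
    fluorophore: str
    target: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def parse_probe_manifest(source) -> list[ProbeRecord]:
    """Parse a probe manifest (CSV or TSV with header) into validated records.

    Required columns: probe_id, sequence, fluorophore, target.  Sequences
    are uppercased and must be nonempty over the A/C/G/T/U alphabet; an
    invalid character raises with the offending row and character named.
    """
    df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"probe_id", "sequence", "fluorophore", "target"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe manifest lacks columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        seq = str(row["sequence"]).strip().upper()
        if not seq or seq == "NAN":
            raise ValueError(f"row {i}: empty probe sequence")
        for ch in seq:
            if ch not in VALID_BASES:
                raise ValueError(f"row {i}: invalid nucleotide {ch!r} in sequence")
        records.append(
            ProbeRecord(
                probe_id=str(row["probe_id"]).strip(),
                sequence=seq,
                fluorophore=str(row["fluorophore"]).strip(),
                target=str(row["target"]).strip(),
            )
        )
    return records
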