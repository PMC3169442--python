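"""qPCR readouts: ddCt relative expression, ChIP-qPCR enrichment, replicate
summaries and the two-tailed Student t-test with significance flags.

Relative expression follows the classic ddCt scheme with amplification
efficiency fixed at 2.0 per cycle (primer efficiencies ~100%):

    dCt(sample)  = mean Ct(target) - mean Ct(reference gene)
    ddCt(sample) = dCt(sample) - dCt(control sample)
    fold         = 2 ** (-ddCt)

Replicate SDs are combined in Ct space as sqrt(sd_target^2 + sd_reference^2)
and mapped through 2**(-x) at mean +/- sd; the reported fold SD is half the
resulting range.  ChIP enrichment is expressed as percent of input,
100 * 2**(Ct_input_adjusted - Ct_IP), optionally divided by the pan-H3
percent-of-input at the same amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError, UndefinedStatisticError

CT_COLUMNS = ("sample", "target", "replicate", "ct")
CHIP_COLUMNS = ("sample", "assay", "target", "replicate", "ct")


def read_ct_table(path, sep: str = "\t", chip: bool = False) -> pd.DataFrame:
    """Read a delimited Ct table with a header row and validate it."""
    table = pd.read_csv(Path(path), sep=sep)
    return validate_ct_table(table, chip=chip)


def validate_ct_table(table: pd.DataFrame, chip: bool = False) -> pd.DataFrame:
    required = CHIP_COLUMNS if chip else CT_COLUMNS
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise DataError(f"Ct table is missing column(s): {missing}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise DataError("all Ct values must be finite and > 0")
    out = table.copy()
    out["ct"] = ct.astype(float)
    return out


def replicate_summary(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator); SD is NaN when n == 1."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DataError("replicate_summary requires at least one value")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return mean, sd


def _per_sample_stats(table: pd.DataFrame, gene: str) -> pd.DataFrame:
    sub = table[table["target"] == gene]
    grouped = sub.groupby("sample")["ct"].agg(["mean", "std", "count"])
    return grouped


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference_gene: str,
    control_sample: str,
) -> pd.DataFrame:
    """Relative expression of ``target`` per sample, normalized to the
    reference gene and expressed relative to the control sample.

    Returns one row per sample with columns ``sample, target, fold, sd,
    dct, ddct``; the control sample's fold is exactly 1 by construction.
    A machine offset added to every Ct cancels.
    """
    table = validate_ct_table(table)
    t_stats = _per_sample_stats(table, target)
    r_stats = _per_sample_stats(table, reference_gene)
    samples = list(dict.fromkeys(table["sample"]))
    if control_sample not in samples:
        raise DataError(f"control sample {control_sample!r} not in table")
    for s in samples:
        if s not in t_stats.index:
            raise DataError(f"sample {s!r} has no rows for target {target!r}")
        if s not in r_stats.index:
            raise DataError(
                f"sample {s!r} has no rows for reference gene {reference_gene!r}"
            )
    dct = t_stats["mean"] - r_stats["mean"]
    ddct = dct - dct[control_sample]
    sd_ct = np.sqrt(t_stats["std"] ** 2 + r_stats["std"] ** 2)
    rows = []
    for s in samples:
        fold = float(2.0 ** (-ddct[s]))
        if np.isnan(sd_ct[s]):
            sd = float("nan")
        else:
            hi = 2.0 ** (-(ddct[s] - sd_ct[s]))
            lo = 2.0 ** (-(ddct[s] + sd_ct[s]))
            sd = float((hi - lo) / 2.0)
        rows.append(
            {"sample": s, "target": target, "fold": fold, "sd": sd,
             "dct": float(dct[s]), "ddct": float(ddct[s])}
        )
    return pd.DataFrame(rows)


def chip_enrichment(
    table: pd.DataFrame,
    antibody_target: str,
    input_label: str = "input",
    mode: str = "percent_input",
    h3_label: str = "H3",
    input_fraction: float = 1.0,
) -> pd.DataFrame:
    """ChIP-qPCR enrichment per (sample, amplicon).

    ``table`` has columns ``sample, assay, target, replicate, ct`` where
    ``assay`` names the antibody (or ``input_label``) and ``target`` the
    amplicon.  ``percent_input`` = 100 * 2**(Ct_input_adj - Ct_IP) with
    Ct_input_adj = Ct_input - log2(1 / input_fraction) correcting for the
    fraction of chromatin reserved as input.  ``relative_to_h3`` divides
    the mark's percent-of-input by pan-H3 percent-of-input at the same
    amplicon.
    """
    table = validate_ct_table(table, chip=True)
    if mode not in ("percent_input", "relative_to_h3"):
        raise ParameterError(f"unknown mode {mode!r}")
    if not (0 < input_fraction <= 1):
        raise ParameterError("input_fraction must be in (0, 1]")
    dilution = float(np.log2(1.0 / input_fraction))

    def percent(sample: str, amplicon: str, assay: str) -> tuple[float, float]:
        ip = table[(table["sample"] == sample) & (table["target"] == amplicon)
                   & (table["assay"] == assay)]["ct"]
        inp = table[(table["sample"] == sample) & (table["target"] == amplicon)
                    & (table["assay"] == input_label)]["ct"]
        if inp.empty:
            raise DataError(f"no input rows for ({sample!r}, {amplicon!r})")
        if ip.empty:
            raise DataError(f"no {assay!r} rows for ({sample!r}, {amplicon!r})")
        d_ct = (inp.mean() - dilution) - ip.mean()
        sd_ct = np.sqrt(np.nan_to_num(ip.std() ** 2) + np.nan_to_num(inp.std() ** 2))
        return float(100.0 * 2.0 ** d_ct), float(sd_ct)

    pairs = (
        table[table["assay"] == antibody_target][["sample", "target"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    rows = []
    for sample, amplicon in pairs:
        value, sd_ct = percent(sample, amplicon, antibody_target)
        if mode == "relative_to_h3":
            h3_value, h3_sd = percent(sample, amplicon, h3_label)
            sd_ct = float(np.sqrt(sd_ct**2 + h3_sd**2))
            value = value / h3_value
        center = value
        hi = center * 2.0**sd_ct
        lo = center * 2.0**-sd_ct
        rows.append(
            {"sample": sample, "target": amplicon, "enrichment": center,
             "sd": (hi - lo) / 2.0, "mode": mode}
        )
    return pd.DataFrame(rows)


@dataclass
class TTestResult:
    t: float
    p: float
    flag: str          # 'ns', '*' (p < 0.05) or '**' (p < 0.01)
    df: float


def significance_flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def two_tailed_ttest(a, b, equal_var: bool = True) -> TTestResult:
    """Two-sample two-tailed Student t-test (equal-variance by default;
    ``equal_var=False`` gives Welch's variant).

    Raises :class:`UndefinedStatisticError` when the pooled variance is zero
    rather than silently reporting t = 0.
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("each group needs at least 2 values")
    na, nb = x.size, y.size
    va, vb = x.var(ddof=1), y.var(ddof=1)
    if equal_var:
        df = float(na + nb - 2)
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        se2 = va / na + vb / nb
        se = np.sqrt(se2)
        if se > 0:
            df = float(se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
        else:
            df = float(na + nb - 2)
    if se == 0:
        raise UndefinedStatisticError(
            "pooled variance is zero; the t statistic is undefined"
        )
    t = float((x.mean() - y.mean()) / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=t, p=p, flag=significance_flag(p), df=df)
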