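"""RT-PCR validation arithmetic: band-intensity ratios and group tests.

Multiplex RT-PCR products quantified by capillary gel electrophoresis give
one fluorescent band intensity per transcript species per lane.  Two
ratio kinds are defined:

* relative normalized gene expression — band of the transcript of
  interest divided by the GAPDH control band;
* relative normalized expression ratio — band of the alternative
  (androgen-regulated) transcript divided by the constitutive band, or
  the 3' transcript end divided by the 5' end.

Ratios are computed per lane and compared between control and treated
replicate lanes with an independent-sample t-test, significant at
p < 0.05 (strict).
"""

from __future__ import annotations

import pandas as pd

from .diffexp import student_t_test

__all__ = [
    "BAND_ROLES",
    "RATIO_KINDS",
    "relative_normalized_gene_expression",
    "relative_normalized_expression_ratio",
    "lane_ratios",
    "compare_ratio_groups",
    "validation_rate",
    "read_band_table",
    "write_band_table",
]

BAND_ROLES = ("alternative", "constitutive", "end3", "end5", "target", "control_gapdh")

#: numerator / denominator band roles per ratio kind
RATIO_KINDS = {
    "gene_expression": ("target", "control_gapdh"),
    "alt_vs_const": ("alternative", "constitutive"),
    "end3_vs_end5": ("end3", "end5"),
}

BAND_COLUMNS = ("sample_id", "condition", "lane", "role", "intensity")


def _ratio(bands, num_role: str, den_role: str) -> float:
    try:
        num = float(bands[num_role])
        den = float(bands[den_role])
    except KeyError as exc:
        raise KeyError(f"band role {exc.args[0]!r} missing from lane") from exc
    if num < 0 or den < 0:
        raise ValueError("band intensities must be non-negative")
    if den == 0:
        raise ZeroDivisionError(f"denominator band {den_role!r} is zero")
    return num / den


def relative_normalized_gene_expression(bands) -> float:
    """Transcript-of-interest band over the GAPDH control band."""
    return _ratio(bands, "target", "control_gapdh")


def relative_normalized_expression_ratio(bands, kind: str) -> float:
    """Alternative/constitutive or 3'-end/5'-end band ratio per ``kind``."""
    if kind not in ("alt_vs_const", "end3_vs_end5"):
        raise ValueError(f"unknown ratio kind {kind!r}")
    num_role, den_role = RATIO_KINDS[kind]
    return _ratio(bands, num_role, den_role)


def lane_ratios(band_table: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Per-lane ratios of the requested kind from a long-format band table."""
    if kind not in RATIO_KINDS:
        raise ValueError(f"unknown ratio kind {kind!r}")
    num_role, den_role = RATIO_KINDS[kind]
    rows = []
    for (sample, condition, lane), sub in band_table.groupby(
        ["sample_id", "condition", "lane"]
    ):
        bands = dict(zip(sub["role"], sub["intensity"]))
        rows.append(
            {
                "sample_id": sample,
                "condition": condition,
                "lane": lane,
                "ratio": _ratio(bands, num_role, den_role),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "condition", "lane", "ratio"])


def compare_ratio_groups(control_ratios, treated_ratios, alpha: float = 0.05):
    """Independent-sample t-test on lane ratios; significant iff p < alpha."""
    t, p = student_t_test(treated_ratios, control_ratios)
    return t, p, p < alpha


def validation_rate(n_validated: int, n_candidates: int) -> float:
    """Percentage of candidates that validated experimentally."""
    if n_candidates <= 0:
        raise ValueError("need at least one candidate")
    if not 0 <= n_validated <= n_candidates:
        raise ValueError("validated count must be between 0 and the candidate count")
    return 100.0 * n_validated / n_candidates


def read_band_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(BAND_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"band table missing columns: {sorted(missing)}")
    unknown = set(df["role"]) - set(BAND_ROLES)
    if unknown:
        raise ValueError(f"unknown band roles: {sorted(unknown)}")
    if (df["intensity"] < 0).any():
        raise ValueError("band intensities must be non-negative")
    return df


def write_band_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(BAND_COLUMNS))
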