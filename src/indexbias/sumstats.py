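"""Reading, harmonizing, filtering and pruning GWAS summary statistics.

The adjustment works on two per-variant tables: an incidence scan (log odds
ratios or linear betas for disease occurrence) and a prognosis scan (effects
on a subsequent outcome, estimated conditional on incidence, e.g. among
cases only).  Both must refer to the same effect allele before the slope
regression is meaningful, so harmonization flips signs where the allele
coding differs and drops variants whose alleles cannot be reconciled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default column mapping for :func:`read_sumstats`
DEFAULT_COLUMNS = {
    "variant_id": "SNP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "beta": "BETA",
    "se": "SE",
}

#: optional columns; absent from the file -> NaN
OPTIONAL_COLUMNS = {"eaf": "EAF", "info": "INFO", "chrom": "CHR", "pos": "POS"}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(ValueError):
    """Malformed or unusable summary statistics input."""


@dataclass
class ReadReport:
    """Bookkeeping for rows dropped while reading a table."""

    n_read: int = 0
    n_kept: int = 0
    n_bad_se: int = 0
    n_bad_beta: int = 0
    n_duplicate: int = 0


@dataclass
class HarmonizeReport:
    n_incidence: int = 0
    n_prognosis: int = 0
    n_common: int = 0
    n_flipped: int = 0
    n_palindromic_dropped: int = 0
    n_mismatch_dropped: int = 0
    n_pairs: int = 0


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read one GWAS summary-statistics table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Maps canonical names (``variant_id``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se``, optionally ``eaf``, ``info``,
        ``chrom``, ``pos``) to the column names used in the file.  Entries
        omitted fall back to :data:`DEFAULT_COLUMNS` / :data:`OPTIONAL_COLUMNS`.
    sep
        Field separator; ``None`` autodetects tab/whitespace.

    Returns
    -------
    (DataFrame, ReadReport)
        Frame with canonical column names, one row per retained variant.
        Rows with unparseable or non-positive standard errors, unparseable
        betas, or duplicated variant IDs (first kept) are dropped and
        counted in the report.
    """
    cmap = dict(DEFAULT_COLUMNS)
    cmap.update({k: v for k, v in OPTIONAL_COLUMNS.items()})
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+", engine="python")
    if df.shape[0] == 0:
        raise SumstatsError(f"no data rows in {path}")

    for canon in DEFAULT_COLUMNS:
        if cmap[canon] not in df.columns:
            raise SumstatsError(
                f"required column {cmap[canon]!r} (for {canon}) not in header of {path}; "
                f"header: {list(df.columns)}"
            )

    out = pd.DataFrame()
    for canon, col in cmap.items():
        if col in df.columns:
            out[canon] = df[col]
        elif canon in OPTIONAL_COLUMNS:
            out[canon] = np.nan

    report = ReadReport(n_read=len(out))
    for col in ("beta", "se", "eaf", "info"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    bad_beta = out["beta"].isna()
    bad_se = out["se"].isna() | (out["se"] <= 0)
    report.n_bad_beta = int((bad_beta & ~bad_se).sum())
    report.n_bad_se = int(bad_se.sum())
    out = out[~(bad_beta | bad_se)]

    out["variant_id"] = out["variant_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        out[col] = out[col].astype(str).str.upper()
    dup = out["variant_id"].duplicated()
    report.n_duplicate = int(dup.sum())
    out = out[~dup].reset_index(drop=True)
    report.n_kept = len(out)
    logger.info(
        "read %d rows from %s: kept %d, dropped %d (se), %d (beta), %d (duplicate id)",
        report.n_read, path, report.n_kept, report.n_bad_se, report.n_bad_beta,
        report.n_duplicate,
    )
    if report.n_kept == 0:
        raise SumstatsError(f"no usable rows in {path}")
    return out, report


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return oa == ea.map(_COMPLEMENT)


def harmonize(
    incidence: pd.DataFrame,
    prognosis: pd.DataFrame,
    drop_palindromic: bool = True,
) -> tuple[pd.DataFrame, HarmonizeReport]:
    """Align the two scans onto a shared effect allele.

    Only variants present in both tables are kept.  Where the prognosis
    scan's effect/other alleles are swapped relative to incidence, the
    prognosis beta is negated and its allele frequency replaced by 1-eaf.
    Palindromic variants (A/T, C/G) are dropped by default because strand
    cannot be resolved; variants whose allele sets do not match even after
    a swap are dropped and counted.

    Returns a pair table with columns ``variant_id, effect_allele,
    other_allele, beta_gx, se_gx, beta_gy_prime, se_gy, eaf, info_x,
    info_y, chrom, pos, pruned`` (``pruned`` initialised False) and a
    :class:`HarmonizeReport`.
    """
    report = HarmonizeReport(n_incidence=len(incidence), n_prognosis=len(prognosis))
    inc = incidence.set_index("variant_id", drop=False)
    pro = prognosis.set_index("variant_id", drop=False)
    common = inc.index.intersection(pro.index)
    report.n_common = len(common)
    if len(common) == 0:
        raise SumstatsError("no variants shared between incidence and prognosis tables")
    inc = inc.loc[common]
    pro = pro.loc[common]

    same = (pro["effect_allele"] == inc["effect_allele"]) & (
        pro["other_allele"] == inc["other_allele"]
    )
    swapped = (pro["effect_allele"] == inc["other_allele"]) & (
        pro["other_allele"] == inc["effect_allele"]
    )
    keep = same | swapped
    report.n_mismatch_dropped = int((~keep).sum())
    report.n_flipped = int((swapped & keep).sum())

    beta_gy = pro["beta"].where(same, -pro["beta"])
    eaf_y = pro["eaf"].where(same, 1.0 - pro["eaf"])

    pairs = pd.DataFrame(
        {
            "variant_id": inc["variant_id"],
            "effect_allele": inc["effect_allele"],
            "other_allele": inc["other_allele"],
            "beta_gx": inc["beta"],
            "se_gx": inc["se"],
            "beta_gy_prime": beta_gy,
            "se_gy": pro["se"],
            "eaf": inc["eaf"].fillna(eaf_y),
            "info_x": inc["info"],
            "info_y": pro["info"],
            "chrom": inc["chrom"],
            "pos": inc["pos"],
        }
    )[keep]

    if drop_palindromic:
        pal = _is_palindromic(pairs["effect_allele"], pairs["other_allele"])
        report.n_palindromic_dropped = int(pal.sum())
        pairs = pairs[~pal]

    pairs = pairs.reset_index(drop=True)
    pairs["pruned"] = False
    report.n_pairs = len(pairs)
    logger.info(
        "harmonized %d/%d shared variants: %d sign-flipped, %d palindromic dropped, "
        "%d allele-mismatch dropped",
        report.n_pairs, report.n_common, report.n_flipped,
        report.n_palindromic_dropped, report.n_mismatch_dropped,
    )
    return pairs, report


def filter_pairs(
    pairs: pd.DataFrame, min_info: float = 0.0, min_eaf: float = 0.0
) -> pd.DataFrame:
    """Filter harmonized pairs on imputation quality and allele frequency.

    A pair passes when ``info_x`` and ``info_y`` are both >= ``min_info``
    and ``eaf`` lies in ``[min_eaf, 1 - min_eaf]``.  A missing info or eaf
    passes only when the corresponding threshold is 0 (conservative: do not
    silently admit unknown-quality variants).
    """
    if not (0.0 <= min_info <= 1.0) or not (0.0 <= min_eaf <= 0.5):
        raise ValueError("min_info must be in [0,1] and min_eaf in [0,0.5]")
    keep = pd.Series(True, index=pairs.index)
    if min_info > 0:
        keep &= (pairs["info_x"] >= min_info) & (pairs["info_y"] >= min_info)
    if min_eaf > 0:
        keep &= (pairs["eaf"] >= min_eaf) & (pairs["eaf"] <= 1.0 - min_eaf)
    out = pairs[keep.fillna(False)].reset_index(drop=True)
    if len(out) == 0:
        logger.warning("filter_pairs removed every variant")
    return out


def greedy_ld_prune(
    dosages: np.ndarray,
    variant_ids,
    r2_threshold: float = 0.1,
    window: int = 250,
) -> list:
    """Greedy left-to-right LD pruning on a dosage matrix.

    Scans columns (assumed ordered by genomic position) once; a variant is
    retained iff its squared Pearson correlation with every previously
    retained variant among the trailing ``window`` retained columns is
    below ``r2_threshold``.  Zero-variance columns are skipped with a
    warning (their correlation is undefined).

    Returns the retained variant IDs, preserving input order.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    if window < 1:
        raise ValueError("window must be >= 1")
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if len(variant_ids) != m:
        raise ValueError("variant_ids length must match number of dosage columns")

    centred = dosages - dosages.mean(axis=0)
    norms = np.sqrt((centred**2).sum(axis=0))
    kept_idx: list[int] = []
    for j in range(m):
        if norms[j] == 0:
            logger.warning("variant %s has zero variance; excluded from pruning",
                           variant_ids[j])
            continue
        ok = True
        for k in kept_idx[-window:]:
            r = centred[:, j] @ centred[:, k] / (norms[j] * norms[k])
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept_idx.append(j)
    return [variant_ids[j] for j in kept_idx]


def flag_pruned(pairs: pd.DataFrame, pruned_ids) -> pd.DataFrame:
    """Mark the slope-estimation subset; returns a copy with ``pruned`` set."""
    out = pairs.copy()
    out["pruned"] = out["variant_id"].isin(set(pruned_ids))
    return out


ADJUSTED_COLUMNS = [
    "variant_id", "beta_gx", "se_gx", "beta_gy_prime", "se_gy",
    "beta_gy_adj", "se_adj", "z", "p",
]


def write_adjusted(records: pd.DataFrame, path) -> None:
    """Write adjusted results as a tab-delimited table.

    Uses 17 significant digits (``%.17g``) so a round trip through text
    reproduces every float bit-exactly, and keeps tiny p-values (1e-300)
    from underflowing to 0 in the output.
    """
    records.loc[:, ADJUSTED_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_adjusted(path) -> pd.DataFrame:
    """Read a table written by :func:`write_adjusted`."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str},
                     float_precision="round_trip")
    missing = [c for c in ADJUSTED_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsError(f"adjusted table {path} lacks columns {missing}")
    return df


def read_id_list(path) -> list[str]:
    """Read a plain-text variant-ID list, one ID per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
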