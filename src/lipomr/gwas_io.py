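"""Reading, harmonizing and pruning GWAS summary statistics.

The reader takes an explicit column map with conventional defaults because
no universal summary-statistics dialect exists across consortia. Alleles
are restricted to single-base A/C/G/T (indels and multi-allelic records are
rejected at load), which keeps the strand/swap logic exact.

Harmonization expresses every trait's effect on a common effect allele per
variant, flipping beta signs (and folding allele frequencies) where a
source reports the swapped allele pair, and either dropping strand-ambiguous
(A/T, C/G) variants or resolving them by allele frequency.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    PALINDROMIC_PAIRS,
    VALID_ALLELES,
    ConfigurationError,
    DataError,
    GeneRegion,
    HarmonizedPanel,
    LDMatrix,
    SummaryStatSet,
    VariantAssociation,
)

DEFAULT_COLUMNS = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
}
REQUIRED = ("variant_id", "effect_allele", "other_allele", "beta", "se")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class LoadReport:
    """Row-level accounting for a summary-statistics load."""

    n_read: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def __str__(self) -> str:
        detail = ", ".join(f"{k}={v}" for k, v in sorted(self.dropped.items()))
        return f"{self.n_dropped} dropped of {self.n_read}" + (
            f" ({detail})" if detail else ""
        )


def _sniff_sep(path) -> str | None:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def read_summary_stats(
    path,
    trait_name: str,
    trait_type: str = "quantitative",
    column_map: dict[str, str] | None = None,
) -> tuple[SummaryStatSet, LoadReport]:
    """Load one trait's summary statistics from a delimited text table.

    Rows with non-positive SE or with alleles outside single-base A/C/G/T
    are dropped and counted in the returned :class:`LoadReport`; a
    duplicated variant_id is an error.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={cmap["variant_id"]: str})
    if df.empty:
        raise DataError(f"{path}: empty summary-statistics table")
    missing = [k for k in REQUIRED if cmap[k] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: required columns missing: "
            + ", ".join(f"{k} (mapped to {cmap[k]!r})" for k in missing)
        )

    report = LoadReport(n_read=len(df))
    records: list[VariantAssociation] = []
    seen: set[str] = set()
    has = {k: cmap[k] in df.columns for k in cmap}
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        vid = str(row[cmap["variant_id"]])
        ea = str(row[cmap["effect_allele"]]).upper()
        oa = str(row[cmap["other_allele"]]).upper()
        se = float(row[cmap["se"]])
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES or ea == oa:
            report.drop("invalid_alleles")
            continue
        if not np.isfinite(se) or se <= 0:
            report.drop("nonpositive_se")
            continue
        if vid in seen:
            raise DataError(f"duplicate variant_id {vid!r} in {path}")
        seen.add(vid)

        def opt(key, cast):
            if not has[key]:
                return None
            val = row[cmap[key]]
            return None if pd.isna(val) else cast(val)

        eaf = opt("eaf", float)
        if eaf is not None and not (0.0 < eaf < 1.0):
            report.drop("eaf_out_of_range")
            continue
        records.append(
            VariantAssociation(
                variant_id=vid,
                effect_allele=ea,
                other_allele=oa,
                beta=float(row[cmap["beta"]]),
                se=se,
                chrom=opt("chrom", str),
                pos=opt("pos", int),
                eaf=eaf,
                pvalue=opt("pvalue", float),
                n=opt("n", float),
            )
        )
    report.n_kept = len(records)
    if not records:
        raise DataError(f"{path}: no usable rows after filtering ({report})")
    return SummaryStatSet(trait_name, trait_type, records), report


def read_ld_matrix(path) -> LDMatrix:
    """Load LD as a square matrix (header row of ids) or long triplets (id1, id2, r)."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    cols = [c.lower() for c in df.columns]
    if len(df.columns) == 3 and ("r" in cols or "corr" in cols):
        id1, id2, rcol = df.columns
        ids = sorted(set(df[id1].astype(str)) | set(df[id2].astype(str)))
        lookup = {v: i for i, v in enumerate(ids)}
        mat = np.eye(len(ids))
        for a, b, r in zip(df[id1].astype(str), df[id2].astype(str), df[rcol]):
            mat[lookup[a], lookup[b]] = mat[lookup[b], lookup[a]] = float(r)
        return LDMatrix(ids, mat)
    ids = [str(c) for c in df.columns]
    return LDMatrix(ids, df.to_numpy(dtype=float))


def read_gene_regions(path, flank_bp: int = 0) -> list[GeneRegion]:
    """Load 4-column gene annotation (gene, chrom, start, end)."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    need = {"gene", "chrom", "start", "end"}
    if not need.issubset({c.lower() for c in df.columns}):
        raise ConfigurationError(f"{path}: gene annotation needs columns {sorted(need)}")
    df.columns = [c.lower() for c in df.columns]
    return [
        GeneRegion(str(r.gene), str(r.chrom), int(r.start), int(r.end), flank_bp)
        for r in df.itertuples(index=False)
    ]


def _aligned(rec: VariantAssociation, ref: VariantAssociation) -> tuple[float, float | None, str] | None:
    """Express ``rec`` on ``ref``'s effect allele.

    Returns (beta, eaf, action) or None if the allele pairs are
    irreconcilable. Strand flips (complementary allele pairs) are handled;
    palindromic pairs are resolved by the caller.
    """
    ea, oa = rec.effect_allele, rec.other_allele
    if (ea, oa) == (ref.effect_allele, ref.other_allele):
        return rec.beta, rec.eaf, "kept"
    if (oa, ea) == (ref.effect_allele, ref.other_allele):
        return -rec.beta, None if rec.eaf is None else 1 - rec.eaf, "beta_flipped"
    cea, coa = ea.translate(_COMPLEMENT), oa.translate(_COMPLEMENT)
    if (cea, coa) == (ref.effect_allele, ref.other_allele):
        return rec.beta, rec.eaf, "strand_flipped"
    if (coa, cea) == (ref.effect_allele, ref.other_allele):
        return -rec.beta, None if rec.eaf is None else 1 - rec.eaf, "strand_and_beta_flipped"
    return None


def harmonize(
    exposures: list[SummaryStatSet],
    outcome: SummaryStatSet,
    drop_palindromic: bool = True,
    eaf_threshold: float = 0.08,
) -> HarmonizedPanel:
    """Align exposures and outcome onto common variants and effect alleles.

    The first exposure's allele coding is the reference. Palindromic (A/T,
    C/G) variants are dropped when ``drop_palindromic`` is set; otherwise a
    variant is retained if both the reference and the other source report an
    allele frequency on the same side of 0.5 and both are farther than
    ``eaf_threshold`` from 0.5 (frequencies on opposite sides imply the
    swapped orientation, triggering a beta flip); ambiguous cases are
    dropped. All actions are recorded in ``alignment_log``.
    """
    if not exposures:
        raise ConfigurationError("at least one exposure is required")
    sets = list(exposures) + [outcome]
    maps = [s.by_id() for s in sets]
    common = [v for v in sets[0].by_id() if all(v in m for m in maps[1:])]
    if not common:
        raise DataError("no variants shared by all exposures and the outcome")

    log: list[dict] = []
    kept_ids: list[str] = []
    rows_bX, rows_seX, rows_pX = [], [], []
    bY, seY = [], []
    chroms, poss = [], []
    any_p = all(
        all(m[v].pvalue is not None for v in common) for m in maps[:-1]
    )

    for vid in common:
        ref = maps[0][vid]
        if ref.is_palindromic and drop_palindromic:
            log.append({"variant_id": vid, "action": "dropped", "detail": "palindromic"})
            continue
        betas, ps = [ref.beta], [ref.pvalue]
        ses = [ref.se]
        ok = True
        detail = []
        for m in maps[1:]:
            rec = m[vid]
            res = _aligned(rec, ref)
            if res is None:
                log.append({"variant_id": vid, "action": "dropped", "detail": "allele mismatch"})
                ok = False
                break
            beta, eaf, action = res
            if ref.is_palindromic:
                # strand is unknowable from alleles: fall back on frequency
                ref_eaf, rec_eaf = ref.eaf, rec.eaf
                if (
                    ref_eaf is None
                    or rec_eaf is None
                    or abs(ref_eaf - 0.5) <= eaf_threshold
                    or abs(rec_eaf - 0.5) <= eaf_threshold
                ):
                    log.append(
                        {"variant_id": vid, "action": "dropped", "detail": "palindromic, eaf inconclusive"}
                    )
                    ok = False
                    break
                same_side = (ref_eaf - 0.5) * (rec_eaf - 0.5) > 0
                beta = rec.beta if same_side else -rec.beta
                action = "eaf_aligned" if same_side else "eaf_aligned_flipped"
            betas.append(beta)
            ses.append(rec.se)
            ps.append(rec.pvalue)
            detail.append(action)
        if not ok:
            continue
        kept_ids.append(vid)
        rows_bX.append(betas[:-1])
        rows_seX.append(ses[:-1])
        rows_pX.append(ps[:-1])
        bY.append(betas[-1])
        seY.append(ses[-1])
        chroms.append(ref.chrom)
        poss.append(ref.pos)
        log.append({"variant_id": vid, "action": "kept", "detail": ";".join(detail) or "kept"})

    if not kept_ids:
        raise DataError("no variants survived harmonization")
    have_pos = all(p is not None for p in poss)
    return HarmonizedPanel(
        variant_ids=kept_ids,
        exposure_names=[s.trait_name for s in exposures],
        bX=np.array(rows_bX, dtype=float),
        seX=np.array(rows_seX, dtype=float),
        bY=np.array(bY, dtype=float),
        seY=np.array(seY, dtype=float),
        pX=np.array(rows_pX, dtype=float) if any_p else None,
        chrom=[c if c is not None else "" for c in chroms],
        pos=np.array(poss, dtype=int) if have_pos else None,
        outcome_name=outcome.trait_name,
        alignment_log=pd.DataFrame(log, columns=["variant_id", "action", "detail"]),
    )


def select_instruments(
    panel: HarmonizedPanel,
    p_threshold: float = 5e-8,
    rule: str = "any_exposure",
    exposure: str | None = None,
) -> HarmonizedPanel:
    """Keep variants genome-wide significant for the rule's exposure set.

    ``rule="any_exposure"`` retains a variant if its minimum p-value across
    all exposures is below ``p_threshold``; ``rule="named_exposure"``
    considers only ``exposure``. Order is preserved.
    """
    if panel.pX is None:
        raise ConfigurationError("panel carries no exposure p-values")
    if rule == "any_exposure":
        minp = panel.pX.min(axis=1)
    elif rule == "named_exposure":
        if exposure is None:
            raise ConfigurationError("named_exposure rule requires an exposure name")
        minp = panel.pX[:, panel.exposure_index(exposure)]
    else:
        raise ConfigurationError(f"unknown rule {rule!r}")
    keep = np.flatnonzero(minp < p_threshold)
    if keep.size == 0:
        raise DataError(f"no instruments pass p < {p_threshold:g}")
    return panel.take(keep)


def ld_prune(
    panel: HarmonizedPanel,
    ld: LDMatrix,
    r2_threshold: float,
) -> HarmonizedPanel:
    """Greedy LD pruning ranked by minimum exposure p-value.

    Variants are visited in ascending order of their minimum exposure
    p-value (ties broken lexicographically by variant_id); a variant is
    kept iff its squared correlation with every previously kept variant is
    below ``r2_threshold``. Deterministic given the input.
    """
    idx = ld.index_of(panel.variant_ids)
    sub = ld.r[np.ix_(idx, idx)]
    if panel.pX is not None:
        rank_key = panel.pX.min(axis=1)
    else:
        # fall back on instrument strength: largest |z| first
        rank_key = -np.abs(panel.bX / panel.seX).max(axis=1)
    order = sorted(
        range(panel.n_variants), key=lambda j: (rank_key[j], panel.variant_ids[j])
    )
    kept: list[int] = []
    for j in order:
        if all(sub[j, i] ** 2 < r2_threshold for i in kept):
            kept.append(j)
    kept.sort()  # preserve original panel order
    return panel.take(kept)


def write_panel(panel: HarmonizedPanel, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def write_alignment_log(panel: HarmonizedPanel, path) -> None:
    panel.alignment_log.to_csv(path, sep="\t", index=False)
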