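"""Reading and writing of site-count tables, sample/ploidy descriptions and scan output.

The count-file dialect is a self-documented, tab-separated table with one row
per variant site::

    chrom  pos_bp  panel0_A  panel0_a  panel1_A  panel1_a  dist  s<i>_A  s<i>_a ...

``panel0``/``panel1`` are allele counts in the two unadmixed reference panels
(panel 1 is the donor / introgressing population throughout this package).
``dist`` is by default the genetic distance in Morgans from the previous site
(0 for the first site of a chromosome); it may alternatively hold a per-bp
recombination rate, selected by ``dist_unit="rate"`` and normalised to Morgans
on read.  Each sample contributes two observation columns: read counts of the
A and a allele in pileup mode, or allele dosages summing to the ploidy in
genotype mode.  Coordinates are 1-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleSet",
    "DemographicModel",
    "SiteTable",
    "read_counts_file",
    "write_counts_file",
    "read_ploidy_file",
    "write_ploidy_file",
    "write_scan_output",
    "vcf_to_counts",
]

#: canonical fixed columns of a count table
FIXED_COLUMNS = ["chrom", "pos_bp", "panel0_A", "panel0_a", "panel1_A", "panel1_a", "dist"]

# float format used when serialising genetic distances; chosen so that
# write∘read is the identity on files produced by this module.
_DIST_FMT = "%.10g"


@dataclass(frozen=True)
class SampleSet:
    """Sample identifiers with per-sample ploidy.

    Ploidy is 1 for inbred/haploid samples, 2 for outbred diploids, and the
    number of pooled chromosomes for a pooled observation column (in which
    case ``pooled`` is set and a single sample is present).
    """

    ids: tuple[str, ...]
    ploidies: tuple[int, ...]
    pooled: bool = False

    def __post_init__(self):
        if len(self.ids) != len(self.ploidies):
            raise ValueError("ids and ploidies must have equal length")
        if any(p < 1 for p in self.ploidies):
            raise ValueError("ploidies must be >= 1")
        if self.pooled and len(self.ids) != 1:
            raise ValueError("pooled mode implies a single observation column")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def diploid(cls, n: int) -> "SampleSet":
        return cls(tuple(f"s{i}" for i in range(n)), (2,) * n)

    @classmethod
    def pool(cls, n_chrom: int, sample_id: str = "pool") -> "SampleSet":
        return cls((sample_id,), (n_chrom,), pooled=True)


@dataclass(frozen=True)
class DemographicModel:
    """One-pulse admixture model: a single donor pulse of fraction ``m`` into a
    population of effective size ``Ne`` diploids, ``t`` generations before
    sampling."""

    Ne: float
    m: float
    t: float

    def __post_init__(self):
        if not self.Ne > 0:
            raise ValueError("Ne must be positive")
        if not 0.0 < self.m < 1.0:
            raise ValueError("m must lie in (0, 1)")
        if not self.t >= 1:
            raise ValueError("t must be >= 1 generation")

    def flipped(self) -> "DemographicModel":
        """Model seen after swapping donor and recipient labels (m -> 1-m)."""
        return DemographicModel(self.Ne, 1.0 - self.m, self.t)


class SiteTable:
    """Ordered per-site records for one or more chromosomes.

    Thin wrapper around a :class:`pandas.DataFrame` with the fixed columns of
    the count-file dialect plus two observation columns per sample.  Rows are
    sorted by (chrom, pos_bp); cumulative genetic positions are exposed via
    :meth:`pos_morgans`.
    """

    def __init__(self, df: pd.DataFrame, samples: SampleSet):
        missing = [c for c in FIXED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        expected = FIXED_COLUMNS + [c for s in samples.ids for c in (f"{s}_A", f"{s}_a")]
        df = df.loc[:, expected].reset_index(drop=True)
        _validate(df)
        self.df = df
        self.samples = samples

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def pos_bp(self) -> np.ndarray:
        return self.df["pos_bp"].to_numpy()

    def pos_morgans(self) -> np.ndarray:
        """Cumulative genetic position in Morgans (per chromosome)."""
        out = np.empty(len(self.df))
        for _, idx in self.df.groupby("chrom", sort=False).groups.items():
            out[np.asarray(idx)] = np.cumsum(self.df.loc[idx, "dist"].to_numpy())
        return out

    def panel_counts(self, panel: int) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.df[f"panel{panel}_A"].to_numpy(),
            self.df[f"panel{panel}_a"].to_numpy(),
        )

    def obs(self, sample_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(n_A, n_a) observation columns for one sample."""
        return (
            self.df[f"{sample_id}_A"].to_numpy(),
            self.df[f"{sample_id}_a"].to_numpy(),
        )

    def drop_uncovered_panels(self) -> tuple["SiteTable", int]:
        """Drop sites where either reference panel has zero sampled alleles.

        The emission mixture is undefined for a missing panel; the number of
        dropped sites is returned so callers can log it.  Genetic distances of
        dropped sites are folded into the following site so cumulative map
        positions are preserved.
        """
        tot0 = self.df["panel0_A"] + self.df["panel0_a"]
        tot1 = self.df["panel1_A"] + self.df["panel1_a"]
        keep = ((tot0 > 0) & (tot1 > 0)).to_numpy()
        if keep.all():
            return self, 0
        df = self.df.copy()
        pos_m = self.pos_morgans()
        df = df.loc[keep].reset_index(drop=True)
        # recompute per-chromosome distances from retained cumulative positions
        kept_pos = pos_m[keep]
        for _, idx in df.groupby("chrom", sort=False).groups.items():
            idx = np.asarray(idx)
            d = np.diff(kept_pos[idx], prepend=kept_pos[idx[0]])
            df.loc[idx, "dist"] = d
        return SiteTable(df, self.samples), int((~keep).sum())


def _validate(df: pd.DataFrame) -> None:
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if len(pos) and (np.diff(pos) <= 0).any():
            i = int(np.flatnonzero(np.diff(pos) <= 0)[0])
            row = sub.index[i + 1]
            raise ValueError(
                f"positions not strictly increasing on {chrom!r}: row {row + 1} "
                f"(pos {pos[i + 1]} after {pos[i]})"
            )
    if (df["dist"] < 0).any():
        raise ValueError("negative genetic distance")
    count_cols = [c for c in df.columns if c not in ("chrom", "pos_bp", "dist")]
    if (df[count_cols] < 0).to_numpy().any():
        raise ValueError("negative count encountered")


def read_counts_file(
    path, samples: SampleSet | None = None, dist_unit: str = "morgans"
) -> SiteTable:
    """Read a count file; returns a :class:`SiteTable` (with its SampleSet).

    ``dist_unit`` selects the interpretation of the distance column:
    ``"morgans"`` (Morgans to previous site, the native dialect) or ``"rate"``
    (per-bp recombination rate, converted to Morgans using the bp gap to the
    previous site).  If ``samples`` is omitted, sample count is inferred from
    the column count and all samples are assumed diploid.
    """
    rows = []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if n_cols is None:
                n_cols = len(parts)
                if n_cols < 9 or (n_cols - 7) % 2:
                    raise ValueError(
                        f"{path}: expected 7 fixed + 2k observation columns, got {n_cols}"
                    )
            elif len(parts) != n_cols:
                raise ValueError(f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}")
            try:
                row = [parts[0], int(parts[1]), *map(int, parts[2:6]), float(parts[6]),
                       *map(int, parts[7:])]
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed row ({err})") from None
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    n_samples = (n_cols - 7) // 2
    if samples is None:
        samples = SampleSet.diploid(n_samples)
    elif len(samples) != n_samples:
        raise ValueError(
            f"{path}: {n_samples} observation-column pairs but {len(samples)} samples declared"
        )
    cols = FIXED_COLUMNS + [c for s in samples.ids for c in (f"{s}_A", f"{s}_a")]
    df = pd.DataFrame(rows, columns=cols)
    if dist_unit == "rate":
        for _, idx in df.groupby("chrom", sort=False).groups.items():
            idx = np.asarray(idx)
            gaps = np.diff(df.loc[idx, "pos_bp"].to_numpy(), prepend=df.loc[idx[0], "pos_bp"])
            df.loc[idx, "dist"] = df.loc[idx, "dist"].to_numpy() * gaps
    elif dist_unit != "morgans":
        raise ValueError(f"unknown dist_unit {dist_unit!r}")
    try:
        return SiteTable(df, samples)
    except ValueError as err:
        # re-raise with file context; _validate already names the row
        raise ValueError(f"{path}: {err}") from None


def write_counts_file(table: SiteTable, path) -> None:
    """Write the canonical dialect; inverse of :func:`read_counts_file`."""
    df = table.df
    with open(path, "w") as fh:
        fh.write("# introscan counts v1\n")
        fh.write("# " + "\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fields = [str(row[0]), str(row[1])] + [str(int(v)) for v in row[2:6]]
            fields.append(_DIST_FMT % row[6])
            fields += [str(int(v)) for v in row[7:]]
            fh.write("\t".join(fields) + "\n")


def read_ploidy_file(path) -> SampleSet:
    """One line per sample: ``id<TAB>ploidy[<TAB>pooled]``."""
    ids, ploidies, pooled = [], [], False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id ploidy'")
            ids.append(parts[0])
            ploidies.append(int(parts[1]))
            if len(parts) > 2 and parts[2].lower() == "pooled":
                pooled = True
    return SampleSet(tuple(ids), tuple(ploidies), pooled=pooled)


def write_ploidy_file(samples: SampleSet, path) -> None:
    with open(path, "w") as fh:
        for i, (sid, p) in enumerate(zip(samples.ids, samples.ploidies)):
            flag = "\tpooled" if samples.pooled and i == 0 else ""
            fh.write(f"{sid}\t{p}{flag}\n")


def write_scan_output(result, path, params: dict | None = None) -> None:
    """Write per-site scan results as a tab-separated table.

    gss mode: one row per evaluated site (chrom, pos_bp, s_hat, lr, flags);
    grid mode: one row per (site, s) combination.  A ``#`` header records the
    run parameters.
    """
    header = dict(params or {})
    with open(path, "w") as fh:
        fh.write("# introscan scan v1\n")
        for key in sorted(header):
            fh.write(f"# {key}={header[key]}\n")
        if result.mode == "grid":
            fh.write("#chrom\tpos_bp\ts\tlr\tflags\n")
            for rec in result.records():
                fh.write(
                    f"{rec['chrom']}\t{rec['pos_bp']}\t{rec['s']:.6g}\t"
                    f"{rec['lr']:.6f}\t{rec['flags']}\n"
                )
        else:
            fh.write("#chrom\tpos_bp\ts_hat\tlr\tflags\n")
            for rec in result.records():
                fh.write(
                    f"{rec['chrom']}\t{rec['pos_bp']}\t{rec['s_hat']:.6g}\t"
                    f"{rec['lr']:.6f}\t{rec['flags']}\n"
                )


def read_scan_output(path) -> pd.DataFrame:
    """Read a scan output written by :func:`write_scan_output`."""
    names = None
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#chrom"):
                names = line[1:].strip().split("\t")
            elif line.startswith("#") or not line.strip():
                continue
            else:
                rows.append(line.rstrip("\n").split("\t"))
    if names is None:
        raise ValueError(f"{path}: missing column header")
    df = pd.DataFrame(rows, columns=names)
    df["pos_bp"] = df["pos_bp"].astype(int)
    for col in df.columns:
        if col in ("s", "s_hat", "lr"):
            df[col] = df[col].astype(float)
    return df


def vcf_to_counts(vcf_path, panel0_samples, panel1_samples, focal_samples,
                  rec_rate_per_bp: float) -> "SiteTable":  # pragma: no cover - convenience stub
    """Convert a VCF plus panel assignment into a count table.

    Non-core convenience for real-data import: genotype calls for the two
    reference panels are collapsed into allele counts and focal-sample
    genotypes into dosage observations, with a uniform per-bp recombination
    rate.  Requires ``cyvcf2``; not used by the analysis pipeline or tests.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    idx = {s: i for i, s in enumerate(vcf.samples)}
    groups = [[idx[s] for s in g] for g in (panel0_samples, panel1_samples, focal_samples)]
    rows = []
    prev_pos: dict[str, int] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = np.array(var.genotypes)[:, :2]
        counts = []
        for g in groups[:2]:
            sub = gts[g].ravel()
            sub = sub[sub >= 0]
            counts += [int((sub == 0).sum()), int((sub == 1).sum())]
        obs = []
        for i in groups[2]:
            sub = gts[i]
            obs += [int((sub == 0).sum()), int((sub == 1).sum())]
        dist = (var.POS - prev_pos.get(var.CHROM, var.POS)) * rec_rate_per_bp
        prev_pos[var.CHROM] = var.POS
        rows.append([var.CHROM, var.POS, *counts, dist, *obs])
    samples = SampleSet(tuple(focal_samples), (2,) * len(focal_samples))
    cols = FIXED_COLUMNS + [c for s in samples.ids for c in (f"{s}_A", f"{s}_a")]
    return SiteTable(pd.DataFrame(rows, columns=cols), samples)
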