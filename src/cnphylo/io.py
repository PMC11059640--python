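"""File formats, run configuration, and provenance headers.

Formats: Ginkgo-style profile TSV (CHR/START/END then one column per cell,
0-based half-open coordinates), NEXUS tree logs with a taxa translation
table and BEAST-style ``[&rate=...]`` node comments, a tab-separated scalar
trace, and a BED-like event table.  Every file written here carries comment
header lines embedding the tool version, seed, and a hash of the resolved
configuration.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
import tempfile
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .likelihood import CopyNumberMatrix
from .mcmc import ClockModelParams, PriorConfig
from .simulator import CNAEvent, GENOME_LENGTH
from .trees import RootedTimeTree

__all__ = [
    "RunConfig",
    "read_profiles",
    "write_profiles",
    "write_tree_log",
    "read_tree_log",
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
]


@dataclass
class RunConfig:
    """Resolved run configuration shared by the CLI subcommands."""

    seed: int = 1
    k: int = 9
    chain_length: int = 100_000
    sample_every: int = 100
    burnin_fraction: float = 0.2
    n_summary_samples: int = 2000
    likelihood_weight: float = 1.0
    n_chains: int = 1
    delta_T: float = 0.1
    swap_every: int = 100
    bin_subsample_stride: int = 0  # 0 disables; 20 keeps every 20th bin
    bin_subsample_offset: int = 0
    d_bounds: tuple[float, float] = (0.001, 5.0)
    sigma_bounds: tuple[float, float] = (0.0, 9.0)
    rd_bounds: tuple[float, float] = (0.0, 1.0e6)
    re_bounds: tuple[float, float] = (0.0, 1.0)
    lambda_R: float = math.log(2.0)
    alpha_R: float = 0.5
    beta_R: float = 2.0
    move_weights: dict | None = None

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        for name in ("d_bounds", "sigma_bounds", "rd_bounds", "re_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must have positive length")

    def prior_config(self) -> PriorConfig:
        return PriorConfig(tuple(self.d_bounds), tuple(self.sigma_bounds),
                           tuple(self.rd_bounds), tuple(self.re_bounds))

    def clock_params(self) -> ClockModelParams:
        return ClockModelParams(self.lambda_R, self.alpha_R, self.beta_R)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for name in ("d_bounds", "sigma_bounds", "rd_bounds", "re_bounds"):
            if name in data:
                data[name] = tuple(data[name])
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        for name in ("d_bounds", "sigma_bounds", "rd_bounds", "re_bounds"):
            data[name] = list(data[name])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance_lines(config: RunConfig | None, seed: int | None,
                      prefix: str = "#") -> list[str]:
    lines = [f"{prefix} cnphylo {__version__}"]
    if seed is not None:
        lines.append(f"{prefix} seed={seed}")
    if config is not None:
        lines.append(f"{prefix} config_hash={config.config_hash()}")
    return lines


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp_", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ----------------------------------------------------------------------
# profile TSV
# ----------------------------------------------------------------------

def read_profiles(path: str) -> CopyNumberMatrix:
    """Read a Ginkgo-style TSV: CHR, START, END, then one column per cell."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty profile file")
    required = ["CHR", "START", "END"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col}")
    cell_cols = [c for c in df.columns if c not in required]
    if not cell_cols:
        raise ValueError(f"{path}: no cell columns")
    dupes = [c for c in cell_cols if c.endswith(".1") and c[:-2] in cell_cols]
    if dupes or len(set(cell_cols)) != len(cell_cols):
        bad = dupes[0][:-2] if dupes else cell_cols[0]
        raise ValueError(f"{path}: duplicated cell column {bad!r}")
    values = (df[cell_cols].apply(pd.to_numeric, errors="coerce")
              .to_numpy(dtype=float).T)
    bins = df[required].copy()
    bins["START"] = bins["START"].astype(np.int64)
    bins["END"] = bins["END"].astype(np.int64)
    return CopyNumberMatrix(values, cell_cols, bins)


def write_profiles(D: CopyNumberMatrix, path: str,
                   config: RunConfig | None = None,
                   seed: int | None = None) -> None:
    df = D.bins.copy()
    for i, cid in enumerate(D.cell_ids):
        col = D.values[i]
        df[cid] = col.astype(int) if np.all(np.mod(col[~np.isnan(col)], 1) == 0) \
            else col
    header = _provenance_lines(config, seed)
    header.append("# coordinates: 0-based half-open")
    _atomic_write(path, "\n".join(header) + "\n"
                  + df.to_csv(sep="\t", index=False))


# ----------------------------------------------------------------------
# tree logs (NEXUS)
# ----------------------------------------------------------------------

def write_tree_log(trees: list[RootedTimeTree], path: str,
                   config: RunConfig | None = None,
                   seed: int | None = None,
                   iterations: list[int] | None = None) -> None:
    """NEXUS tree log with a taxa translation table and per-node metadata."""
    if not trees:
        raise ValueError("no trees to write")
    taxa = trees[0].leaf_labels()
    index = {lbl: i + 1 for i, lbl in enumerate(sorted(taxa))}
    lines = ["#NEXUS"]
    lines += [f"[{l[2:]}]" for l in _provenance_lines(config, seed)]
    lines.append("Begin taxa;")
    lines.append(f"    Dimensions ntax={len(taxa)};")
    lines.append("    Taxlabels")
    for lbl in sorted(taxa):
        lines.append(f"        {lbl}")
    lines.append("        ;")
    lines.append("End;")
    lines.append("Begin trees;")
    lines.append("    Translate")
    tr = [f"        {i} {lbl}" for lbl, i in sorted(index.items(),
                                                    key=lambda kv: kv[1])]
    lines.append(",\n".join(tr))
    lines.append(";")
    for s, tree in enumerate(trees):
        t = tree.copy()
        for leaf in t.leaves():
            leaf.label = str(index[leaf.label])
        it = iterations[s] if iterations is not None else s
        lines.append(f"tree STATE_{it} = "
                     + t.to_newick(annotations=True))
    lines.append("End;")
    _atomic_write(path, "\n".join(lines) + "\n")


def read_tree_log(path: str) -> tuple[list[RootedTimeTree], list[int]]:
    """Parse a NEXUS tree log written by :func:`write_tree_log`."""
    with open(path) as fh:
        text = fh.read()
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise ValueError(f"{path}: not a NEXUS file")
    translate: dict[str, str] = {}
    trees: list[RootedTimeTree] = []
    iters: list[int] = []
    in_translate = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("translate"):
            in_translate = True
            continue
        if in_translate:
            if line == ";":
                in_translate = False
                continue
            entry = line.rstrip(",;")
            parts = entry.split()
            if len(parts) >= 2:
                translate[parts[0]] = parts[1]
            if line.endswith(";"):
                in_translate = False
            continue
        if low.startswith("tree "):
            name, _, newick = line.partition("=")
            tree = RootedTimeTree.from_newick(newick.strip())
            for leaf in tree.leaves():
                leaf.label = translate.get(leaf.label, leaf.label)
            trees.append(tree)
            state = name.split()[1]
            iters.append(int(state.rsplit("_", 1)[-1])
                         if "_" in state else len(iters))
    if not trees:
        raise ValueError(f"{path}: no trees found")
    return trees, iters


# ----------------------------------------------------------------------
# scalar trace
# ----------------------------------------------------------------------

def write_trace(scalars: pd.DataFrame, path: str,
                config: RunConfig | None = None,
                seed: int | None = None) -> None:
    header = _provenance_lines(config, seed)
    _atomic_write(path, "\n".join(header) + "\n"
                  + scalars.to_csv(sep="\t", index=False))


def read_trace(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ----------------------------------------------------------------------
# events
# ----------------------------------------------------------------------

def write_events(events: list[CNAEvent], path: str,
                 genome_length: float = GENOME_LENGTH,
                 config: RunConfig | None = None,
                 seed: int | None = None) -> None:
    rows = []
    for e in events:
        s, t = e.interval(genome_length)
        rows.append(("linear", int(round(s * genome_length)),
                     int(round(t * genome_length)), e.branch_id,
                     "maternal" if e.allele == 0 else "paternal",
                     "gain" if e.sign > 0 else "loss", f"{e.time:.12g}"))
    df = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "branch",
                                     "allele", "sign", "time"])
    header = _provenance_lines(config, seed)
    _atomic_write(path, "\n".join(header) + "\n"
                  + df.to_csv(sep="\t", index=False))


def read_events(path: str,
                genome_length: float = GENOME_LENGTH) -> list[CNAEvent]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, r in df.iterrows():
        out.append(CNAEvent(int(r["branch"]),
                            0 if r["allele"] == "maternal" else 1,
                            float(r["start_bp"]) / genome_length,
                            float(r["end_bp"] - r["start_bp"]),
                            +1 if r["sign"] == "gain" else -1,
                            float(r["time"])))
    return out
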