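"""Cohort container and plain-text file I/O.

A cohort bundles the phenotype table (age, sex, narrative macro/micro scores,
five cognitive-domain scores plus a general screen) with index-aligned
per-subject matrices: resting-state functional connectivity (FC), node-wise
gray-matter volume (GMV) and white-matter fiber-count matrices (WM), all on
one shared parcellation.

Serialisation is deliberately plain: TSV for tables, one dense TSV per
subject for matrices (or a single ``.npz`` stack), with a sidecar manifest
JSON carrying subject order and the parcellation hash.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .edges import edge_endpoints
from .parcellation import Parcellation

PHENOTYPE_COLUMNS = [
    "subject_id", "age", "sex", "macro_score", "micro_score",
    "mem", "exe", "att", "flu", "spa", "mmse",
]

#: cognitive-domain score columns: episodic memory, executive function,
#: attention, verbal fluency, spatial construction, general screen (MMSE-like)
COGNITIVE_DOMAINS = ["mem", "exe", "att", "flu", "spa", "mmse"]

SYMMETRY_TOL = 1e-10


class AlignmentError(ValueError):
    """Subject ids inconsistent across the cohort's file set."""


class FormatError(ValueError):
    """A matrix or table violates the format contract."""


@dataclass
class Cohort:
    """Index-aligned multimodal cohort.

    Attributes
    ----------
    phenotype : DataFrame with :data:`PHENOTYPE_COLUMNS`.
    fc : (n_subjects, n_nodes, n_nodes) stack of symmetric FC matrices.
    parcellation : shared node table.
    gmv : optional (n_subjects, n_nodes) gray-matter volumes.
    wm : optional (n_subjects, n_nodes, n_nodes) integer fiber counts.
    fc_mode : "r" (raw Pearson, entries in [-1, 1]) or "z" (Fisher-z).
    """

    phenotype: pd.DataFrame = field(repr=False)
    fc: np.ndarray = field(repr=False)
    parcellation: Parcellation
    gmv: np.ndarray | None = field(default=None, repr=False)
    wm: np.ndarray | None = field(default=None, repr=False)
    fc_mode: str = "r"
    _edge_matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # ---- validation ----

    def validate(self) -> None:
        ph = self.phenotype
        missing = set(PHENOTYPE_COLUMNS) - set(ph.columns)
        if missing:
            raise FormatError(f"phenotype table missing columns: {sorted(missing)}")
        na = ph[PHENOTYPE_COLUMNS].isna()
        if na.to_numpy().any():
            rows, cols = np.nonzero(na.to_numpy())
            where = [(str(ph["subject_id"].iloc[r]), PHENOTYPE_COLUMNS[c])
                     for r, c in zip(rows[:5], cols[:5])]
            raise FormatError(f"missing phenotype values (subject, column): {where}")
        n, nn = len(ph), self.parcellation.n_nodes
        if self.fc.shape != (n, nn, nn):
            raise AlignmentError(
                f"fc stack shape {self.fc.shape} != ({n}, {nn}, {nn})")
        if not np.allclose(self.fc, np.swapaxes(self.fc, 1, 2), atol=SYMMETRY_TOL, rtol=0):
            raise FormatError("asymmetric FC matrix beyond tolerance")
        if self.fc_mode == "r":
            off = self.fc.copy()
            idx = np.arange(nn)
            off[:, idx, idx] = 0.0
            if np.abs(off).max() > 1 + 1e-12:
                raise FormatError("raw-r FC values outside [-1, 1]")
        if self.gmv is not None and self.gmv.shape != (n, nn):
            raise AlignmentError(f"gmv shape {self.gmv.shape} != ({n}, {nn})")
        if self.wm is not None:
            if self.wm.shape != (n, nn, nn):
                raise AlignmentError(f"wm stack shape {self.wm.shape} != ({n}, {nn}, {nn})")
            if np.any(self.wm < 0):
                raise FormatError("negative WM fiber counts")

    # ---- accessors ----

    @property
    def n_subjects(self) -> int:
        return len(self.phenotype)

    @property
    def n_nodes(self) -> int:
        return self.parcellation.n_nodes

    @property
    def subject_ids(self) -> list[str]:
        return self.phenotype["subject_id"].astype(str).tolist()

    @property
    def ages(self) -> np.ndarray:
        return self.phenotype["age"].to_numpy(dtype=float)

    def score(self, name: str) -> np.ndarray:
        if name not in self.phenotype.columns:
            raise KeyError(f"unknown phenotype {name!r}")
        return self.phenotype[name].to_numpy(dtype=float)

    @property
    def edge_matrix(self) -> np.ndarray:
        """(n_subjects, n_edges) upper-triangle view of the FC stack (cached)."""
        if self._edge_matrix is None:
            r, c = edge_endpoints(self.n_nodes)
            self._edge_matrix = np.ascontiguousarray(self.fc[:, r, c])
        return self._edge_matrix

    def subset(self, idx) -> "Cohort":
        """Cohort restricted to subject positions ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return Cohort(
            phenotype=self.phenotype.iloc[idx].reset_index(drop=True),
            fc=self.fc[idx],
            parcellation=self.parcellation,
            gmv=None if self.gmv is None else self.gmv[idx],
            wm=None if self.wm is None else self.wm[idx],
            fc_mode=self.fc_mode,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _write_matrix_dir(stack: np.ndarray, subject_ids, directory: Path,
                      parc_hash: str, fmt: str = "%.8g") -> None:
    directory.mkdir(parents=True, exist_ok=True)
    for sid, mat in zip(subject_ids, stack):
        np.savetxt(directory / f"{sid}.tsv", mat, delimiter="\t", fmt=fmt)
    manifest = {"subject_ids": list(map(str, subject_ids)), "parcellation_hash": parc_hash}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _read_matrix_dir(directory: Path, subject_ids, n_nodes: int) -> np.ndarray:
    directory = Path(directory)
    if directory.suffix == ".npz" or directory.is_file():
        with np.load(directory, allow_pickle=False) as z:
            stack = z["stack"]
            ids = [str(s) for s in z["subject_ids"]]
        order = {s: i for i, s in enumerate(ids)}
        try:
            sel = [order[str(s)] for s in subject_ids]
        except KeyError as e:
            raise AlignmentError(f"subject {e} missing from {directory}") from e
        return stack[sel]
    out = np.empty((len(subject_ids), n_nodes, n_nodes))
    for k, sid in enumerate(subject_ids):
        path = directory / f"{sid}.tsv"
        if not path.exists():
            raise AlignmentError(f"matrix file missing for subject {sid!r} in {directory}")
        mat = np.loadtxt(path, delimiter="\t")
        if mat.shape != (n_nodes, n_nodes):
            raise FormatError(f"{path}: shape {mat.shape}, expected ({n_nodes}, {n_nodes})")
        out[k] = mat
    return out


def save_cohort(cohort: Cohort, out_dir: str | Path, matrix_format: str = "tsv") -> Path:
    """Write a cohort as a plain-text file set (or npz stacks)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.phenotype.to_csv(out / "phenotype.tsv", sep="\t", index=False)
    cohort.parcellation.to_tsv(out / "parcellation.tsv")
    h = cohort.parcellation.content_hash()
    sids = cohort.subject_ids
    if matrix_format == "npz":
        np.savez_compressed(out / "fc.npz", stack=cohort.fc,
                            subject_ids=np.array(sids))
        if cohort.wm is not None:
            np.savez_compressed(out / "wm.npz", stack=cohort.wm,
                                subject_ids=np.array(sids))
    else:
        _write_matrix_dir(cohort.fc, sids, out / "fc", h)
        if cohort.wm is not None:
            _write_matrix_dir(cohort.wm, sids, out / "wm", h, fmt="%d")
    if cohort.gmv is not None:
        gmv = pd.DataFrame(cohort.gmv, columns=[f"node_{i + 1}" for i in range(cohort.n_nodes)])
        gmv.insert(0, "subject_id", sids)
        gmv.to_csv(out / "gmv.tsv", sep="\t", index=False)
    meta = {"fc_mode": cohort.fc_mode, "parcellation_hash": h,
            "matrix_format": matrix_format}
    (out / "cohort.json").write_text(json.dumps(meta, indent=1))
    return out


def load_cohort(
    phenotype_path: str | Path | None = None,
    fc_path: str | Path | None = None,
    gmv_path: str | Path | None = None,
    wm_path: str | Path | None = None,
    parcellation_path: str | Path | None = None,
    directory: str | Path | None = None,
    fc_mode: str | None = None,
) -> Cohort:
    """Load and validate a cohort from explicit paths or a save_cohort directory."""
    if directory is not None:
        d = Path(directory)
        phenotype_path = phenotype_path or d / "phenotype.tsv"
        parcellation_path = parcellation_path or d / "parcellation.tsv"
        if fc_path is None:
            fc_path = d / "fc.npz" if (d / "fc.npz").exists() else d / "fc"
        if gmv_path is None and (d / "gmv.tsv").exists():
            gmv_path = d / "gmv.tsv"
        if wm_path is None:
            if (d / "wm.npz").exists():
                wm_path = d / "wm.npz"
            elif (d / "wm").exists():
                wm_path = d / "wm"
        meta_path = d / "cohort.json"
        if fc_mode is None and meta_path.exists():
            fc_mode = json.loads(meta_path.read_text()).get("fc_mode", "r")
    if phenotype_path is None or fc_path is None or parcellation_path is None:
        raise ValueError("phenotype, fc and parcellation paths are required")
    parc = Parcellation.from_tsv(parcellation_path)
    ph = pd.read_csv(phenotype_path, sep="\t")
    sids = ph["subject_id"].astype(str).tolist()
    fc = _read_matrix_dir(Path(fc_path), sids, parc.n_nodes)
    gmv = None
    if gmv_path is not None:
        gt = pd.read_csv(gmv_path, sep="\t")
        g_ids = gt["subject_id"].astype(str).tolist()
        if g_ids != sids:
            raise AlignmentError("gmv subject order does not match phenotype table")
        gmv = gt.drop(columns="subject_id").to_numpy(dtype=float)
    wm = None
    if wm_path is not None:
        wm = _read_matrix_dir(Path(wm_path), sids, parc.n_nodes)
    return Cohort(phenotype=ph, fc=fc, parcellation=parc, gmv=gmv, wm=wm,
                  fc_mode=fc_mode or "r")


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-variable mean/sd, age correlation, plus FC value summary.

    Degenerate cases are reported rather than raised: zero-variance columns
    are flagged, and correlations are NaN for n < 2.
    """
    rows = []
    age = cohort.ages
    numeric = [c for c in PHENOTYPE_COLUMNS if c not in ("subject_id", "sex")]
    for col in numeric:
        x = cohort.score(col)
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")
        if len(x) < 2 or sd == 0 or np.std(age) == 0:
            r_age = float("nan")
        else:
            r_age = float(np.corrcoef(age, x)[0, 1])
        rows.append({"variable": col, "mean": float(np.mean(x)), "sd": sd,
                     "corr_age": r_age, "constant": bool(sd == 0)})
    ev = cohort.edge_matrix
    rows.append({"variable": "fc_edges", "mean": float(ev.mean()),
                 "sd": float(ev.std()), "corr_age": float("nan"),
                 "constant": False})
    return pd.DataFrame(rows)
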