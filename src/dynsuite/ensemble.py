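"""NMR-ensemble coordinate metrics: pairwise RMSD over atom selections.

A deposited NMR "structure" is a family of models; the precision of any
fragment is conventionally quoted as the mean +/- SD of the pairwise RMSD

    RMSD_ab = sqrt( sum_i |x_i^a - x_i^b|^2 / n )

over all N(N-1)/2 unordered model pairs, for a stated atom selection.
Families are deposited already superimposed, so the default is to compare
coordinates as they stand (`superpose="none"`); optional modes re-superpose
each pair on the selection itself or on a separate reference selection
(e.g. the well-defined core backbone) before measuring.

Selections use a small query language:
``chain A and resname SAH and fragment met and heavy`` -- predicates are
`chain <id>`, `resname <name>`, `resnum <n>` / `resnum <a>-<b>`,
`name <atom>[,<atom>...]`, `heavy`, `backbone`, `fragment met|adenosine`
(the amino-acid and nucleoside moieties of SAH/SAM), `all`, combined with
`and`, `or`, `not` and parentheses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = ["Ensemble", "read_ensemble", "pairwise_rmsd", "RMSDResult",
           "SAH_MET_FRAGMENT", "SAH_ADENOSINE_FRAGMENT"]

#: heavy atoms of the methionine (amino-acid) moiety of SAH/SAM
SAH_MET_FRAGMENT = {"N", "CA", "CB", "CG", "SD", "C", "O", "OXT"}
#: heavy atoms of the adenosine moiety of SAH/SAM
SAH_ADENOSINE_FRAGMENT = {
    "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
    "N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4",
}
_BACKBONE = {"N", "CA", "C", "O"}


@dataclass
class Ensemble:
    """Multi-model coordinate set with a shared atom table.

    `atoms` has columns chain, res_num, res_name, name, element;
    `coords` has shape (n_models, n_atoms, 3) in angstroms.
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self):
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords shape inconsistent with atom table")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, query: str) -> np.ndarray:
        """Boolean mask over the atom table for a selection expression."""
        mask = _parse_selection(query, self.atoms)
        return mask

    def subset(self, query: str) -> "Ensemble":
        mask = self.select(query)
        return Ensemble(self.atoms[mask].reset_index(drop=True), self.coords[:, mask])


# --------------------------------------------------------------------------
# selection language

def _tokenize(query: str) -> list[str]:
    out = []
    for raw in query.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


def _predicate(tokens: list[str], atoms: pd.DataFrame) -> np.ndarray:
    tok = tokens.pop(0).lower()
    if tok == "(":
        mask = _or_expr(tokens, atoms)
        if not tokens or tokens.pop(0) != ")":
            raise ValueError("unbalanced parenthesis in selection")
        return mask
    if tok == "not":
        return ~_predicate(tokens, atoms)
    if tok == "all":
        return np.ones(len(atoms), dtype=bool)
    if tok == "heavy":
        elem = atoms["element"].astype(str).str.upper()
        return (~elem.isin(["H", "D"])).to_numpy()
    if tok == "backbone":
        return atoms["name"].isin(_BACKBONE).to_numpy()
    if tok == "chain":
        return (atoms["chain"].astype(str) == tokens.pop(0)).to_numpy()
    if tok == "resname":
        return (atoms["res_name"].astype(str) == tokens.pop(0).upper()).to_numpy()
    if tok == "resnum":
        arg = tokens.pop(0)
        if "-" in arg or ":" in arg:
            a, b = arg.replace(":", "-").split("-")
            return atoms["res_num"].between(int(a), int(b)).to_numpy()
        return (atoms["res_num"] == int(arg)).to_numpy()
    if tok == "name":
        names = [n.strip().upper() for n in tokens.pop(0).split(",")]
        return atoms["name"].astype(str).str.upper().isin(names).to_numpy()
    if tok == "fragment":
        frag = tokens.pop(0).lower()
        if frag in ("met", "methionine"):
            names = SAH_MET_FRAGMENT
        elif frag in ("adenosine", "ade"):
            names = SAH_ADENOSINE_FRAGMENT
        else:
            raise ValueError(f"unknown fragment '{frag}' (expected met or adenosine)")
        return atoms["name"].astype(str).str.upper().isin(names).to_numpy()
    raise ValueError(f"unknown selection keyword '{tok}'")


def _and_expr(tokens: list[str], atoms: pd.DataFrame) -> np.ndarray:
    mask = _predicate(tokens, atoms)
    while tokens and tokens[0].lower() == "and":
        tokens.pop(0)
        mask = mask & _predicate(tokens, atoms)
    return mask


def _or_expr(tokens: list[str], atoms: pd.DataFrame) -> np.ndarray:
    mask = _and_expr(tokens, atoms)
    while tokens and tokens[0].lower() == "or":
        tokens.pop(0)
        mask = mask | _and_expr(tokens, atoms)
    return mask


def _parse_selection(query: str, atoms: pd.DataFrame) -> np.ndarray:
    tokens = _tokenize(query)
    if not tokens:
        raise ValueError("empty selection expression")
    mask = _or_expr(tokens, atoms)
    if tokens:
        raise ValueError(f"trailing tokens in selection: {tokens}")
    return mask


# --------------------------------------------------------------------------
# reading

def read_ensemble(path) -> Ensemble:
    """Read a multi-model PDB or mmCIF file into an :class:`Ensemble`.

    Heteroatoms (ligands) are retained; alternative locations are resolved to
    the highest-occupancy conformer. All models must share one atom table.
    """
    st = gemmi.read_structure(str(path))
    if len(st) < 1:
        raise ValueError(f"{path}: no models found")
    tables, coord_sets = [], []
    for model in st:
        rows, xyz = [], []
        for chain in model:
            for res in chain:
                best: dict[str, gemmi.Atom] = {}
                for atom in res:
                    prev = best.get(atom.name)
                    if prev is None or atom.occ > prev.occ:
                        best[atom.name] = atom
                for name in sorted(best):
                    atom = best[name]
                    rows.append(
                        (chain.name, res.seqid.num, res.name, name, atom.element.name)
                    )
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        tables.append(rows)
        coord_sets.append(np.asarray(xyz, dtype=float))
    ref = tables[0]
    for i, tab in enumerate(tables[1:], start=2):
        if tab != ref:
            extra = sorted(set(tab) ^ set(ref))[:10]
            raise ValueError(
                f"{path}: model {i} atom table differs from model 1; "
                f"offending atoms (up to 10): {extra}"
            )
    atoms = pd.DataFrame(ref, columns=["chain", "res_num", "res_name", "name", "element"])
    return Ensemble(atoms=atoms, coords=np.stack(coord_sets))


# --------------------------------------------------------------------------
# pairwise RMSD

@dataclass
class RMSDResult:
    mean: float  # angstrom
    sd: float
    n_pairs: int
    n_atoms: int
    superpose: str
    per_pair: np.ndarray


def _superpose(mobile: np.ndarray, target: np.ndarray, fit_mobile: np.ndarray,
               fit_target: np.ndarray) -> np.ndarray:
    """Rigid-body fit of `mobile` onto `target` using the fit-atom subsets."""
    mc, tc = fit_mobile.mean(axis=0), fit_target.mean(axis=0)
    rot, _ = Rotation.align_vectors(fit_target - tc, fit_mobile - mc)
    return rot.apply(mobile - mc) + tc


def pairwise_rmsd(
    ensemble: Ensemble,
    selection: str,
    superpose: str = "none",
    reference_selection: str | None = None,
) -> RMSDResult:
    """Mean +/- SD pairwise RMSD of a selection over all model pairs.

    superpose: "none" (deposited alignment), "selection"/"on-selection"
    (re-superpose each pair on the measured atoms), or
    "reference"/"on-reference-set" (superpose on `reference_selection`,
    measure on `selection`).
    """
    mode = {"on-selection": "selection", "on-reference-set": "reference"}.get(
        superpose, superpose
    )
    if mode not in ("none", "selection", "reference"):
        raise ValueError(f"unknown superposition mode '{superpose}'")
    if ensemble.n_models < 2:
        raise ValueError("pairwise RMSD needs at least 2 models")
    mask = ensemble.select(selection)
    if not mask.any():
        raise ValueError(f"selection '{selection}' matches no atoms")
    sel = ensemble.coords[:, mask]
    if mode == "reference":
        if not reference_selection:
            raise ValueError("reference superposition requires reference_selection")
        rmask = ensemble.select(reference_selection)
        if not rmask.any():
            raise ValueError(f"selection '{reference_selection}' matches no atoms")
        ref = ensemble.coords[:, rmask]
    vals = []
    for a, b in itertools.combinations(range(ensemble.n_models), 2):
        xa, xb = sel[a], sel[b]
        if mode == "selection":
            xb = _superpose(xb, xa, xb, xa)
        elif mode == "reference":
            xb = _superpose(xb, xa, ref[b], ref[a])
        vals.append(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
    vals = np.asarray(vals)
    return RMSDResult(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        n_pairs=len(vals),
        n_atoms=int(mask.sum()),
        superpose=mode,
        per_pair=vals,
    )
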