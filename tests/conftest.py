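"""Shared fixtures: forward-modelled relaxation records and toy PDB ensembles.

All coordinate fixtures are synthetic, generated at test time; nothing here
is a deposited structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dynsuite.spin import DynamicsParams, SpinConstants, predict_rates

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def constants() -> SpinConstants:
    return SpinConstants()


@pytest.fixture(scope="session")
def relax_record(constants):
    """Factory: one residue's relaxation row(s) forward-modelled from truth.

    Fractional sigma applies to R1/R2; the NOE sigma is absolute. Rates are
    noiseless (the sigmas only weight the fit) unless an rng is given.
    """

    def make(
        s2,
        tau_e=0.0,
        rex=0.0,
        tau_c=10.4e-9,
        sig_frac=0.02,
        sig_noe=0.02,
        res_num=1,
        field_MHz=700.0,
        rng=None,
        sf2=None,
        tau_s=None,
    ) -> pd.DataFrame:
        const = constants.with_field(field_MHz)
        model = "M5" if sf2 is not None else "M4"
        p = DynamicsParams(s2=s2, tau_c=tau_c, tau_e=tau_e, rex=rex,
                           sf2=sf2, tau_s=tau_s, model=model)
        r = predict_rates(p, const)
        r1, r2, noe = r.R1, r.R2, r.NOE
        if rng is not None:
            r1 += rng.normal(0, sig_frac * r.R1)
            r2 += rng.normal(0, sig_frac * r.R2)
            noe += rng.normal(0, sig_noe)
        return pd.DataFrame(
            [
                {
                    "res_num": res_num,
                    "res_name": "ALA",
                    "field_MHz": field_MHz,
                    "R1": r1,
                    "R1_err": sig_frac * r.R1,
                    "R2": r2,
                    "R2_err": sig_frac * r.R2,
                    "NOE": noe,
                    "NOE_err": sig_noe,
                }
            ]
        )

    return make


def _pdb_atom(serial, name, res, chain, resnum, xyz, elem, het=False):
    rec = "HETATM" if het else "ATOM  "
    x, y, z = xyz
    return (
        f"{rec}{serial:>5} {name:<4} {res:>3} {chain}{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2}"
    )


#: heavy atoms of a complete SAH ligand (amino-acid + adenosine moieties)
SAH_ATOMS = [
    ("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("SD", "S"),
    ("C", "C"), ("O", "O"),
    ("C5'", "C"), ("C4'", "C"), ("O4'", "O"), ("C3'", "C"), ("O3'", "O"),
    ("C2'", "C"), ("O2'", "O"), ("C1'", "C"),
    ("N9", "N"), ("C8", "C"), ("N7", "N"), ("C5", "C"), ("C6", "C"),
    ("N6", "N"), ("N1", "N"), ("C2", "C"), ("N3", "N"), ("C4", "C"),
]


@pytest.fixture(scope="session")
def make_pdb_text():
    """Factory for synthetic multi-model PDB text.

    `perturb(model_index, atom_index, base_xyz) -> xyz` positions each atom;
    the default places atoms on a line and displaces nothing.
    """

    def build(n_models=2, perturb=None, with_sah=False, drop_atom_in_model=None):
        rng_base = np.arange(3, dtype=float)
        lines = []
        for m in range(n_models):
            lines.append(f"MODEL     {m + 1:>4}")
            serial = 1
            protein = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
            for resnum in (1, 2):
                for name, elem in protein:
                    base = np.array([serial * 1.3, resnum * 2.0, 0.0])
                    xyz = perturb(m, serial, base) if perturb else base
                    lines.append(_pdb_atom(serial, name, "ALA", "A", resnum, xyz, elem))
                    serial += 1
            if with_sah:
                for i, (name, elem) in enumerate(SAH_ATOMS):
                    if drop_atom_in_model == (m, name):
                        continue
                    base = np.array([10.0 + 1.2 * i, 5.0 + 0.3 * i, 2.0])
                    xyz = perturb(m, serial, base) if perturb else base
                    nm = name if len(name) >= 4 else f"{name:<3}"
                    lines.append(
                        _pdb_atom(serial, nm, "SAH", "A", 300, xyz, elem, het=True)
                    )
                    serial += 1
            lines.append("ENDMDL")
        lines.append("END")
        return "\n".join(lines) + "\n"

    return build


@pytest.fixture
def toy_ensemble_path(tmp_path, make_pdb_text):
    """Two identical models plus one SAH ligand."""
    path = tmp_path / "toy.pdb"
    path.write_text(make_pdb_text(n_models=2, with_sah=True))
    return path
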