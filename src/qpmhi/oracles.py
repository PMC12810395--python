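"""Black-box objective oracles and direction handling.

An :class:`Oracle` evaluates a molecule string to M raw objective values
(deterministic, noise-free).  Directions declare which objectives are
maximized vs minimized; the optimization loop works internally in pure
maximization orientation via :class:`~qpmhi.pareto.MinMaxSpec`.

Shipped oracles:

``logp_tpsa``
    The classic drug-design benchmark pair — maximize the octanol–water
    partition coefficient (logP, favoring membrane permeability) while
    minimizing topological polar surface area (TPSA, favoring passive
    diffusion).  Both are computed locally with RDKit.

``string_pair`` / ``string_pair_anti`` / ``string_pair_pos``
    Fully synthetic pair: smooth functions of the deterministic hash
    embedding of the string, with a tunable cross-objective correlation —
    negative correlation yields a nontrivial trade-off front.  Requires no
    chemistry toolkit and no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .features import hash_features
from .pareto import MinMaxSpec

__all__ = ["Oracle", "get_oracle", "string_objectives", "ORACLES"]


@dataclass(frozen=True)
class Oracle:
    """Named deterministic objective evaluator with direction metadata."""

    name: str
    objective_names: tuple[str, ...]
    directions: tuple[str, ...]
    fn: Callable = field(repr=False)
    aux_names: tuple[str, ...] = ()

    @property
    def m(self) -> int:
        return len(self.objective_names)

    @property
    def minmax(self) -> MinMaxSpec:
        return MinMaxSpec(self.directions)

    def evaluate(self, smiles_list) -> np.ndarray:
        """Raw objective values, (n, M), user orientation."""
        return np.asarray(self.fn(list(smiles_list)), dtype=float)

    def evaluate_internal(self, smiles_list) -> np.ndarray:
        """Objective values in maximization orientation."""
        return self.minmax.apply(self.evaluate(smiles_list))


def _logp_tpsa(smiles_list) -> np.ndarray:
    from rdkit import Chem
    from rdkit.Chem import Crippen, rdMolDescriptors

    out = np.empty((len(smiles_list), 2))
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"oracle cannot evaluate invalid SMILES {smi!r}")
        out[i, 0] = Crippen.MolLogP(mol)
        out[i, 1] = rdMolDescriptors.CalcTPSA(mol)
    return out


def string_objectives(strings, m: int = 2, rho: float = -0.5) -> np.ndarray:
    """Synthetic M-objective ground truth from the string hash embedding.

    With hash coordinates z ~ N(0, I), latent scores are the correlated
    Gaussian mixture

        y_0 = z_0,    y_m = rho z_0 + sqrt(1 - rho^2) z_m   (m >= 1)

    and each objective is a strictly increasing smooth warp of its latent,
    f_m = y_m + 0.3 tanh(y_m).  The monotone warp preserves all dominance
    relations of the latents, so rho = +1 yields co-monotone objectives
    (a single common maximizer) and rho = -1 yields perfect trade-off
    (every point mutually nondominated); intermediate negative rho gives a
    nontrivial Pareto front.  All objectives are already in maximization
    orientation.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    z = hash_features(strings, dim=m + 2)
    y = np.empty((len(strings), m))
    y[:, 0] = z[:, 0]
    for j in range(1, m):
        y[:, j] = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, j]
    return y + 0.3 * np.tanh(y)


def _make_string_oracle(name: str, rho: float) -> Oracle:
    return Oracle(
        name=name,
        objective_names=("s1", "s2"),
        directions=("maximize", "maximize"),
        fn=lambda strings, r=rho: string_objectives(strings, m=2, rho=r),
    )


ORACLES: dict[str, Callable[[], Oracle]] = {
    "logp_tpsa": lambda: Oracle(
        name="logp_tpsa",
        objective_names=("logP", "TPSA"),
        directions=("maximize", "minimize"),
        fn=_logp_tpsa,
    ),
    "string_pair": lambda: _make_string_oracle("string_pair", rho=-0.5),
    "string_pair_anti": lambda: _make_string_oracle("string_pair_anti", rho=-0.9),
    "string_pair_pos": lambda: _make_string_oracle("string_pair_pos", rho=0.9),
}


def get_oracle(name: str) -> Oracle:
    try:
        return ORACLES[name]()
    except KeyError:
        raise ValueError(f"unknown oracle {name!r}; options: {sorted(ORACLES)}")
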