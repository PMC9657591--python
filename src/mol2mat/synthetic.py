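"""Synthetic labelled fingerprint datasets with controllable structure.

Real activity classes differ in how structurally homogeneous they are; the
generator emulates this with class-specific *signature bits*.  Each class owns
``signature_size`` reserved bit positions, set with probability
``p_signature`` for its own molecules, ``p_cross`` for other classes'
molecules; all remaining positions fire at the ``p_background`` rate.  Raising
``p_signature`` (or lowering ``p_background``) makes classes more homogeneous
(higher within-class mean pairwise similarity) and easier to separate.

A small SMILES fixture generator is also provided so the fingerprint engine
can be exercised end-to-end on real molecular graphs without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .fingerprints import LabelledMolecule

__all__ = ["SyntheticConfig", "generate", "generate_branches", "generate_smiles_fixture"]

#: Default per-class molecule counts: ten activity classes whose sizes mirror
#: a typical homogeneous benchmark's class sizes at one-tenth scale.
DEFAULT_CLASS_SIZES = (21, 16, 113, 11, 135, 11, 105, 13, 39, 46)


@dataclass
class SyntheticConfig:
    """Parameters of the signature-bit generator.

    per_class may be a single count (shared by every class) or one count per
    class.
    """

    n_classes: int = 10
    per_class: int | tuple = DEFAULT_CLASS_SIZES
    length: int = 1024
    signature_size: int = 32
    p_signature: float = 0.9
    p_background: float = 0.02
    p_cross: float = 0.05
    seed: int = 0

    def class_sizes(self) -> tuple[int, ...]:
        if np.isscalar(self.per_class):
            return (int(self.per_class),) * self.n_classes
        sizes = tuple(int(c) for c in self.per_class)
        if len(sizes) != self.n_classes:
            raise ValueError(
                f"per_class has {len(sizes)} entries for {self.n_classes} classes"
            )
        return sizes

    def validate(self) -> None:
        if self.n_classes * self.signature_size > self.length:
            raise ValueError(
                f"cannot reserve {self.n_classes} x {self.signature_size} signature bits "
                f"in a length-{self.length} fingerprint"
            )
        for name in ("p_signature", "p_background", "p_cross"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if any(s < 1 for s in self.class_sizes()):
            raise ValueError("every class needs at least one molecule")

    def to_yaml(self) -> str:
        payload = asdict(self)
        if not np.isscalar(payload["per_class"]):
            payload["per_class"] = list(payload["per_class"])
        return yaml.safe_dump(payload)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticConfig":
        payload = yaml.safe_load(text)
        if isinstance(payload.get("per_class"), list):
            payload["per_class"] = tuple(payload["per_class"])
        return cls(**payload)


def generate(config: SyntheticConfig, rng: np.random.Generator | None = None):
    """Draw one labelled binary fingerprint dataset.

    Returns (X, y): X an (N, length) 0/1 integer array, y string labels
    ``class_0..class_{k-1}``.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = config.class_sizes()
    n_total = sum(sizes)
    k, sig = config.n_classes, config.signature_size

    # start from the background rate everywhere, then overwrite signature blocks
    p = np.full((n_total, config.length), config.p_background)
    row = 0
    for c, size in enumerate(sizes):
        block = slice(row, row + size)
        p[block, : k * sig] = config.p_cross
        p[block, c * sig : (c + 1) * sig] = config.p_signature
        row += size
    X = (rng.random((n_total, config.length)) < p).astype(np.int64)
    y = np.repeat([f"class_{c}" for c in range(k)], sizes)
    return X, y


def generate_branches(config: SyntheticConfig, n_branches: int):
    """Draw ``n_branches`` independent fingerprint views of the same molecules.

    Emulates fusing several fingerprint families: every branch shares the
    label vector and class structure but has its own bit realisation (child
    seeds spawned from ``config.seed``).
    """
    if n_branches < 1:
        raise ValueError("need at least one branch")
    children = np.random.SeedSequence(config.seed).spawn(n_branches)
    Xs, y = [], None
    for child in children:
        X, y = generate(config, rng=np.random.default_rng(child))
        Xs.append(X)
    return Xs, y


# --- SMILES fixture ---------------------------------------------------------

_SCAFFOLDS = {
    "benzene": "c1ccccc1",
    "cyclohexane": "C1CCCCC1",
    "indole": "c1ccc2[nH]ccc2c1",
    "naphthalene": "c1ccc2ccccc2c1",
}

_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "O", "OC", "OCC", "N", "NC",
    "F", "Cl", "Br", "C(=O)O", "C(C)C", "S", "SC",
)


def generate_smiles_fixture(n_per_family: int = 4, seed: int = 0) -> list[LabelledMolecule]:
    """Small labelled molecule fixture from substituted scaffold templates.

    Each family is one ring scaffold; members carry different substituents, so
    within-family fingerprints are more similar than between families.  All
    SMILES are valid by construction; deterministic for a fixed seed.
    """
    if n_per_family < 1:
        raise ValueError("n_per_family must be >= 1")
    if n_per_family > len(_SUBSTITUENTS) + 1:
        raise ValueError(f"at most {len(_SUBSTITUENTS) + 1} molecules per family")
    rng = np.random.default_rng(seed)
    molecules = []
    for family, scaffold in _SCAFFOLDS.items():
        candidates = [scaffold] + [sub + scaffold for sub in _SUBSTITUENTS]
        chosen = rng.choice(len(candidates), size=n_per_family, replace=False)
        for i, idx in enumerate(sorted(chosen)):
            molecules.append(
                LabelledMolecule(
                    id=f"{family}_{i}", activity_class=family, smiles=candidates[idx]
                )
            )
    return molecules
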