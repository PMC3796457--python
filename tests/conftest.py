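"""Shared fixtures: independently coded oracles and cached synthetic studies."""

from __future__ import annotations

import pytest

from kanseek.synthetic_data import SyntheticConfig, generate

# Independent IUPAC table for brute-force oracles (typed out, not imported).
ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_scan(seq: str, pattern: str) -> list[tuple[int, str]]:
    """Enumerate every offset x strand and test base membership directly."""
    seq = seq.upper()
    sets = [set(ORACLE_IUPAC[c]) for c in pattern.upper()]
    k = len(pattern)
    hits = []
    for off in range(len(seq) - k + 1):
        window = seq[off : off + k]
        if all(b in s for b, s in zip(window, sets)):
            hits.append((off, "+"))
        rc = "".join(ORACLE_COMPLEMENT.get(b, "?") for b in reversed(window))
        if all(b in s for b, s in zip(rc, sets)):
            hits.append((off, "-"))
    return sorted(hits)


def brute_force_revcomp_pattern(pattern: str) -> str:
    """Complement each symbol's base set, reverse, and re-encode as IUPAC."""
    by_set = {frozenset(v): k for k, v in ORACLE_IUPAC.items()}
    symbols = []
    for sym in reversed(pattern.upper()):
        complemented = frozenset(ORACLE_COMPLEMENT[b] for b in ORACLE_IUPAC[sym])
        symbols.append(by_set[complemented])
    return "".join(symbols)


@pytest.fixture(scope="session")
def small_study():
    """Quick study for structural tests."""
    return generate(SyntheticConfig(seed=3, n_genes=60, n_target_genes=15, n_background_regions=30))


@pytest.fixture(scope="session")
def default_study():
    """The documented default-config study (n_genes=300, n_target=60, seed=7)."""
    return generate(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def mixture_study():
    """2000 planted regions for positional-mixture recovery checks."""
    return generate(
        SyntheticConfig(
            seed=11,
            n_genes=500,
            n_target_genes=500,
            regions_per_target=4,
            n_background_regions=0,
        )
    )
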