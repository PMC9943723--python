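"""Copy-number dosage encodings for the four association models.

A probe's copy-number state is coded −1 (deletion), 0 (copy-neutral) or +1
(duplication), with NaN for missing.  Each association model maps these
states to a numeric dosage so that ordinary regression of a trait on the
dosage tests a specific dosage mechanism:

* ``deletion-only``    — deletion carriers vs copy-neutral; duplications masked.
* ``duplication-only`` — duplication carriers vs copy-neutral; deletions masked.
* ``mirror``           — additive per extra copy (dosage = CN − 2); deletions
  and duplications pull the trait in opposite directions.
* ``U-shape``          — any carrier vs copy-neutral; deletions and
  duplications share one effect direction.

Sign conventions: a positive coefficient always means a higher trait value in
the model's carrier/per-copy direction (carrier-positive for the three
carrier-contrast models, per-additional-copy for mirror).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MODELS = ("deletion-only", "duplication-only", "mirror", "U-shape")

_ALIASES = {
    "del": "deletion-only",
    "deletion-only": "deletion-only",
    "deletion_only": "deletion-only",
    "dup": "duplication-only",
    "duplication-only": "duplication-only",
    "duplication_only": "duplication-only",
    "mirror": "mirror",
    "ushape": "U-shape",
    "u-shape": "U-shape",
    "u_shape": "U-shape",
    "U-shape": "U-shape",
}


def canonical_model(model: str) -> str:
    """Return the canonical model name, raising ``ValueError`` for unknowns."""
    try:
        return _ALIASES[str(model).strip()]
    except KeyError:
        raise ValueError(
            f"unknown association model {model!r}; expected one of {MODELS}"
        ) from None


def encode(states, model: str) -> np.ndarray:
    """Encode copy-number states into the numeric dosage of one model.

    Parameters
    ----------
    states
        Array-like of per-sample states in {−1, 0, +1}, NaN for missing.
    model
        One of ``deletion-only``, ``duplication-only``, ``mirror``,
        ``U-shape`` (short aliases ``del``, ``dup``, ``ushape`` accepted).

    Returns
    -------
    numpy.ndarray of float
        Per-sample dosage; NaN where the state is missing or masked by the
        model (e.g. duplication carriers under ``deletion-only``).
    """
    model = canonical_model(model)
    s = np.asarray(states, dtype=float)
    bad = s[~np.isnan(s)]
    if bad.size and not np.isin(bad, (-1.0, 0.0, 1.0)).all():
        raise ValueError("copy-number states must be in {-1, 0, 1} or NaN")
    out = np.full(s.shape, np.nan)
    if model == "mirror":
        out[:] = s
    elif model == "deletion-only":
        out[s == -1] = 1.0
        out[s == 0] = 0.0
        # duplications stay NaN (disregarded)
    elif model == "duplication-only":
        out[s == 1] = 1.0
        out[s == 0] = 0.0
    else:  # U-shape
        out[np.abs(s) == 1] = 1.0
        out[s == 0] = 0.0
    return out


_PLINK_GENOTYPES = {
    # per model: pseudo-genotype (allele pair) for deletion / neutral / duplication
    "deletion-only": {-1: "T T", 0: "A T", 1: "0 0"},
    "duplication-only": {-1: "0 0", 0: "A T", 1: "T T"},
    "mirror": {-1: "A A", 0: "A T", 1: "T T"},
    "U-shape": {-1: "A A", 0: "A T", 1: "T T"},  # analysed with a het-only contrast
}


def write_plink_transposed(matrix, model: str, path) -> None:
    """Write one model's encoding as a PLINK transposed text genotype file.

    One line per probe: chrom, probe id, genetic distance 0, bp, then an A/T
    pseudo-genotype pair per sample (missing state -> "0 0").  Useful for
    cross-validating the scans against external tooling; the numeric dosage
    used internally is effect-equivalent to the additive coding of these
    pseudo-genotypes (carrier-positive for the U-shape contrast).
    """
    model = canonical_model(model)
    geno = _PLINK_GENOTYPES[model]
    with open(path, "w") as fh:
        for i, probe in enumerate(matrix.probe_ids):
            fields = ["22", str(probe), "0", str(int(matrix.probe_bp[i]))]
            for s in matrix.states[i]:
                fields.append("0 0" if np.isnan(s) else geno[int(s)])
            fh.write("\t".join(fields) + "\n")


def model_consistency_check(results: pd.DataFrame) -> pd.DataFrame:
    """Compare deletion-only and duplication-only effects probe by probe.

    A "true mirror" signal shows opposing deletion/duplication effect signs;
    a U-shape signal shows agreeing signs.  ``results`` must hold columns
    ``probe_id``, ``trait``, ``model`` and ``effect`` (beta, or log(OR) for
    binary traits) covering at least the two single-class models.

    Returns one row per (probe_id, trait) with the two effects and a
    ``verdict`` in {``mirror-like``, ``u-shape-like``, ``indeterminate``}.
    """
    rows = []
    for (probe, trait), grp in results.groupby(["probe_id", "trait"], sort=False):
        by_model = grp.set_index("model")["effect"]
        b_del = by_model.get("deletion-only", np.nan)
        b_dup = by_model.get("duplication-only", np.nan)
        if not (np.isfinite(b_del) and np.isfinite(b_dup)) or b_del == 0 or b_dup == 0:
            verdict = "indeterminate"
        elif np.sign(b_del) != np.sign(b_dup):
            verdict = "mirror-like"
        else:
            verdict = "u-shape-like"
        rows.append(
            {
                "probe_id": probe,
                "trait": trait,
                "beta_del": b_del,
                "beta_dup": b_dup,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows, columns=["probe_id", "trait", "beta_del", "beta_dup", "verdict"])
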