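#!/usr/bin/env python
"""Derive the generator's default allele frequencies from target phenotype
prevalences by Hardy-Weinberg inversion.

Under HWE with per-class allele frequencies f (full), r (reduced) and
i (inactive), the CYP2D6 phenotype shares are PM = i^2,
IM = 2fi + r^2 + 2ri = 2i - 2i^2 + r^2 and NM = f^2 + 2fr; for CYP2C19
with q = freq(inactive) and u = freq(*17): PM = q^2, IM = 2q(1-q),
UM = u^2, NM = the rest.  Only two of the target shares can be matched
per gene (two free parameters), and the CYP2D6 targets are jointly
HWE-inconsistent (PM = 0.0242 forces IM >= 2i - 2i^2 = 0.263), so:

* CYP2C19 uses a relative-weighted least-squares fit over all four shares;
* CYP2D6 fixes a small realistic reduced-allele mass (r = 0.03) and solves
  the NM share (hence the NM vs IM/PM analysis split) exactly.

Prints the class frequencies behind ``pgxtraj.synthetic.DEFAULT_ALLELE_FREQS``.
"""

import numpy as np
from scipy import optimize

# target shares among patients with an established phenotype
CYP2C19_TARGETS = np.array([0.025, 0.209, 0.707, 0.059])  # PM IM NM UM
CYP2D6_TARGETS = np.array([22, 132, 754]) / 908.0          # PM IM NM


def cyp2c19_shares(x):
    q, u = x
    p = 1.0 - q - u
    return np.array([q * q, 2 * q * (1 - q), p * p + 2 * p * u, u * u])


def calibrate_cyp2c19():
    objective = lambda x: (
        ((cyp2c19_shares(x) - CYP2C19_TARGETS) ** 2) / CYP2C19_TARGETS
    ).sum()
    res = optimize.minimize(objective, [0.16, 0.24], method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-15})
    q, u = res.x
    return q, u


def calibrate_cyp2d6(reduced=0.03):
    # match IM+PM (= 1 - NM) exactly given the fixed reduced mass:
    # 2i - i^2 + r^2 = target  ->  i = 1 - sqrt(1 - target + r^2)
    target_im_pm = CYP2D6_TARGETS[0] + CYP2D6_TARGETS[1]
    inactive = 1.0 - np.sqrt(1.0 - target_im_pm + reduced ** 2)
    return inactive, reduced


def main():
    q, u = calibrate_cyp2c19()
    print("CYP2C19: inactive (q) = %.4f, *17 (u) = %.4f, *1 = %.4f"
          % (q, u, 1 - q - u))
    print("  implied shares PM/IM/NM/UM:",
          np.round(cyp2c19_shares([q, u]), 4))
    print("  targets:                  ", CYP2C19_TARGETS)

    i, r = calibrate_cyp2d6()
    f = 1.0 - i - r
    pm = i * i
    im = 2 * i - 2 * i * i + r * r
    print("CYP2D6: inactive = %.4f, reduced = %.4f, full = %.4f" % (i, r, f))
    print("  implied shares PM/IM/NM: [%.4f %.4f %.4f]" % (pm, im, 1 - pm - im))
    print("  targets:                ", np.round(CYP2D6_TARGETS, 4))
    print("  (the PM/IM split is HWE-limited; the NM share is matched exactly)")


if __name__ == "__main__":
    main()
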