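"""Independent high-precision evaluation of the four screening statistics.

Rational parts are computed with exact ``fractions.Fraction`` arithmetic and
only the final transcendental steps (log/exp/sqrt) use floats, so this path
shares no code with the package implementation.
"""

import math
from fractions import Fraction as F


def oracle_stats(a: int, b: int, c: int, d: int, z: float = 1.96) -> dict:
    n = a + b + c + d
    out: dict[str, float] = {}

    if min(a, b, c, d) > 0:
        ror = F(a * d, b * c)
        se = math.sqrt(float(F(1, a) + F(1, b) + F(1, c) + F(1, d)))
        ln_ror = math.log(ror.numerator) - math.log(ror.denominator)
        out["ror"] = float(ror)
        out["ror_lo"] = math.exp(ln_ror - z * se)
        out["ror_hi"] = math.exp(ln_ror + z * se)

    if a > 0 and c > 0:
        prr = F(a, a + b) / F(c, c + d)
        out["prr"] = float(prr)
        se2 = F(1, a) - F(1, a + b) + F(1, c) - F(1, c + d)
        ln_prr = math.log(prr.numerator) - math.log(prr.denominator)
        out["prr_lo"] = math.exp(ln_prr - z * math.sqrt(float(se2)))
        out["prr_hi"] = math.exp(ln_prr + z * math.sqrt(float(se2)))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom > 0:
        out["chi2"] = float(F((a * d - b * c) ** 2 * n, denom))

    gamma = F((n + 2) ** 2, (a + b + 1) * (a + c + 1))
    ratio = F((a + 1) * (n + 2) ** 2) / ((n + gamma) * (a + b + 1) * (a + c + 1))
    eic = math.log2(ratio.numerator) - math.log2(ratio.denominator)
    vic_rational = (
        (b + c + d + gamma - 1) / ((a + 1) * (n + gamma + 1))
        + F(c + d + 1, (a + b + 1) * (n + 3))
        + F(b + d + 1, (a + c + 1) * (n + 3))
    )
    vic = float(vic_rational) / math.log(2) ** 2
    out["gamma"] = float(gamma)
    out["eic"] = eic
    out["vic"] = vic
    out["ic025"] = eic - 2 * math.sqrt(vic)

    if (a + b) > 0 and (a + c) > 0:
        ebgm = F(a * n, (a + c) * (a + b))
        out["ebgm"] = float(ebgm)
        if min(a, b, c, d) > 0:
            se = math.sqrt(float(F(1, a) + F(1, b) + F(1, c) + F(1, d)))
            ln_e = math.log(ebgm.numerator) - math.log(ebgm.denominator)
            out["ebgm05"] = math.exp(ln_e - z * se)
    return out
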