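"""Reference coefficient tables for the MUAC cohort analysis.

These are the published estimates the synthetic-cohort generator is
calibrated to: a constant-dispersion Gaussian GLM baseline (mean model
only), and the joint fit's mean and dispersion submodels.  Values are kept
as the printed strings so tests can recover both the number and its
printed precision (one ulp = one unit in the last printed place).
"""

# Each row: (term, estimate, se, t) as printed strings.
GLM_BASELINE = [
    ("(Intercept)", "3.297646", "1.112371", "2.9645"),
    ("age", "-2.44933", "0.706229", "-3.4682"),
    ("weight", "1.214475", "0.182097", "6.6694"),
    ("height", "0.046291", "0.016303", "2.8394"),
    ("hemoglobin", "0.061822", "0.047596", "1.2989"),
    ("protein", "0.010197", "0.013159", "0.7749"),
    ("albumen", "0.024162", "0.017901", "1.3497"),
    ("weight:height", "-0.007833", "0.002123", "-3.6900"),
    ("age:weight", "-0.024477", "0.028805", "-0.8498"),
    ("age:height", "0.022875", "0.008388", "2.7271"),
]

JOINT_MEAN = [
    ("(Intercept)", "3.514933", "0.699909", "5.022"),
    ("age", "-2.161377", "0.522314", "-4.138"),
    ("weight", "1.194023", "0.127182", "9.388"),
    ("height", "0.028779", "0.008209", "3.506"),
    ("hemoglobin", "0.033497", "0.030733", "1.090"),
    ("protein", "0.016998", "0.011937", "1.424"),
    ("albumen", "0.032157", "0.015628", "2.058"),
    ("weight:height", "-0.006908", "0.001439", "-4.800"),
    ("age:weight", "-0.051909", "0.021880", "-2.372"),
    ("age:height", "0.024228", "0.006006", "4.034"),
]

JOINT_DISPERSION = [
    ("(Intercept)", "-3.686e+00", "1.721319", "-2.1414"),
    ("age", "-4.625e-01", "0.986622", "-0.4687"),
    ("weight", "1.549e-01", "0.256311", "0.6043"),
    ("height", "4.431e-02", "0.027394", "1.6175"),
    ("hemoglobin", "2.719e-01", "0.065510", "4.1505"),
    ("protein", "-4.087e-02", "0.017389", "-2.3503"),
    ("albumen", "3.496e-02", "0.023711", "1.4744"),
    ("weight:height", "-3.353e-03", "0.003065", "-1.0939"),
    ("age:weight", "3.820e-02", "0.044118", "0.8656"),
    ("age:height", "1.095e-05", "0.012225", "0.0009"),
]

ALL_TABLES = {
    "glm_baseline": GLM_BASELINE,
    "joint_mean": JOINT_MEAN,
    "joint_dispersion": JOINT_DISPERSION,
}

# Likelihood function values of the two reference fits.
GLM_MINUS2ML = 464.2776
GLM_MINUS2RL = 527.8103
GLM_CAIC = 484.2776
JOINT_MINUS2ML = 438.4326
JOINT_MINUS2RL = 506.8090
JOINT_CAIC = 458.4326


def ulp(printed: str) -> float:
    """One unit in the last printed place of a decimal or e-notation string."""
    s = printed.lower().lstrip("+-")
    if "e" in s:
        mantissa, exponent = s.split("e")
        exp = int(exponent)
    else:
        mantissa, exp = s, 0
    dp = len(mantissa.split(".")[1]) if "." in mantissa else 0
    return 10.0 ** (exp - dp)
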