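{
  "type": "object",
  "required": ["meta", "descriptives", "correlations", "glm", "joint", "comparison", "diagnostics"],
  "properties": {
    "meta": {
      "type": "object",
      "required": ["n", "method", "mean_terms", "disp_terms"],
      "properties": {
        "n": {"type": "integer"},
        "method": {"type": "string"},
        "mean_terms": {"type": "array", "items": {"type": "string"}},
        "disp_terms": {"type": "array", "items": {"type": "string"}}
      }
    },
    "descriptives": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variable", "minimum", "maximum", "mean", "median", "sd", "n"],
        "properties": {
          "variable": {"type": "string"},
          "minimum": {"type": "number"},
          "maximum": {"type": "number"},
          "mean": {"type": "number"},
          "median": {"type": "number"},
          "sd": {"type": "number"},
          "n": {"type": "integer"}
        }
      }
    },
    "correlations": {
      "type": "object",
      "required": ["labels", "r", "p", "flags"],
      "properties": {
        "labels": {"type": "array", "items": {"type": "string"}},
        "r": {"type": "array", "items": {"type": "array", "items": {"type": "number"}}},
        "p": {"type": "array", "items": {"type": "array"}},
        "flags": {"type": "array", "items": {"type": "array", "items": {"type": "string"}}}
      }
    },
    "glm": {
      "type": "object",
      "required": ["coefficients", "criteria", "converged", "n_iter"],
      "properties": {
        "coefficients": {"type": "array", "items": {"type": "object", "required": ["term", "estimate", "se", "t", "p", "stars"]}},
        "criteria": {"type": "object", "required": ["minus2h", "minus2pbeta", "caic", "aic", "bic", "p_mean", "q_disp", "n"]},
        "converged": {"type": "boolean"},
        "n_iter": {"type": "integer"}
      }
    },
    "joint": {
      "type": "object",
      "required": ["mean_coefficients", "dispersion_coefficients", "criteria", "converged", "n_iter"],
      "properties": {
        "mean_coefficients": {"type": "array", "items": {"type": "object", "required": ["term", "estimate", "se", "t", "p", "stars"]}},
        "dispersion_coefficients": {"type": "array", "items": {"type": "object", "required": ["term", "estimate", "se", "t", "p", "stars"]}},
        "criteria": {"type": "object", "required": ["minus2h", "minus2pbeta", "caic", "aic", "bic", "p_mean", "q_disp", "n"]},
        "converged": {"type": "boolean"},
        "n_iter": {"type": "integer"}
      }
    },
    "comparison": {
      "type": "object",
      "required": ["models", "criteria", "winner"],
      "properties": {
        "models": {"type": "array", "items": {"type": "string"}},
        "criteria": {"type": "array", "items": {"type": "object", "required": ["criterion", "values", "best"]}}
      }
    },
    "diagnostics": {
      "type": "object",
      "required": ["glm", "joint"],
      "properties": {
        "glm": {"type": "object", "required": ["fitted", "std_resid", "abs_resid", "running_mean", "qq", "hist_edges", "hist_counts"]},
        "joint": {"type": "object", "required": ["fitted", "std_resid", "abs_resid", "running_mean", "qq", "hist_edges", "hist_counts"]}
      }
    }
  }
}
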