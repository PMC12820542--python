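{
  "TAM": {
    "nodes": [
      "performance expectancy",
      "effort expectancy",
      "attitude",
      "behavioral intention",
      "actual behavior"
    ],
    "edges": [
      ["effort expectancy", "performance expectancy"],
      ["performance expectancy", "attitude"],
      ["effort expectancy", "attitude"],
      ["performance expectancy", "behavioral intention"],
      ["attitude", "behavioral intention"],
      ["behavioral intention", "actual behavior"]
    ]
  },
  "UTAUT": {
    "nodes": [
      "performance expectancy",
      "effort expectancy",
      "social influence",
      "facilitating conditions",
      "hedonic motivation",
      "financial cost",
      "habit",
      "behavioral intention",
      "actual behavior"
    ],
    "edges": [
      ["performance expectancy", "behavioral intention"],
      ["effort expectancy", "behavioral intention"],
      ["social influence", "behavioral intention"],
      ["facilitating conditions", "behavioral intention"],
      ["hedonic motivation", "behavioral intention"],
      ["financial cost", "behavioral intention"],
      ["habit", "behavioral intention"],
      ["behavioral intention", "actual behavior"],
      ["facilitating conditions", "actual behavior"],
      ["social influence", "actual behavior"]
    ]
  },
  "HBM+PMT": {
    "nodes": [
      "perceived severity",
      "perceived vulnerability",
      "benefits",
      "barriers",
      "self-efficacy",
      "performance expectancy",
      "health",
      "health consciousness",
      "behavioral intention",
      "actual behavior"
    ],
    "edges": [
      ["perceived severity", "behavioral intention"],
      ["perceived vulnerability", "behavioral intention"],
      ["benefits", "behavioral intention"],
      ["barriers", "behavioral intention"],
      ["self-efficacy", "behavioral intention"],
      ["performance expectancy", "behavioral intention"],
      ["health", "behavioral intention"],
      ["health consciousness", "behavioral intention"],
      ["health consciousness", "actual behavior"],
      ["behavioral intention", "actual behavior"]
    ]
  },
  "TTF": {
    "nodes": [
      "task characteristics",
      "technology characteristics",
      "task-technology fit",
      "performance expectancy"
    ],
    "edges": [
      ["task characteristics", "task-technology fit"],
      ["technology characteristics", "task-technology fit"],
      ["task-technology fit", "performance expectancy"]
    ]
  },
  "PCT": {
    "nodes": ["trust", "privacy and security", "behavioral intention"],
    "edges": [
      ["trust", "behavioral intention"],
      ["privacy and security", "behavioral intention"]
    ]
  },
  "TPB": {
    "nodes": [
      "attitude",
      "social influence",
      "self-efficacy",
      "behavioral intention",
      "actual behavior"
    ],
    "edges": [
      ["attitude", "behavioral intention"],
      ["social influence", "behavioral intention"],
      ["self-efficacy", "behavioral intention"],
      ["behavioral intention", "actual behavior"]
    ]
  },
  "DOI": {
    "nodes": [
      "performance expectancy",
      "effort expectancy",
      "compatibility",
      "image",
      "trialability",
      "behavioral intention"
    ],
    "edges": [
      ["performance expectancy", "behavioral intention"],
      ["effort expectancy", "behavioral intention"],
      ["compatibility", "behavioral intention"],
      ["image", "behavioral intention"]
    ]
  }
}
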