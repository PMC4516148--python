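{
  "description": "Reader-study data for 10 uterine-fibroid cases: gold-standard surgical plan (procedure and per-type removal counts), two observers' interpretations from sagittal and surface-rendered (SR) images, and per-observer summary statistics of interpretation time and difficulty. Normalized to one record per case from the source tables.",
  "procedures": ["AM", "LAM", "TLM", "TCR"],
  "cases": [
    {
      "case": 1,
      "gold": {"procedure": "LAM", "removals": {"intramural": 3, "subserosal": 1, "submucosal": 0}},
      "observer1": {"sagittal": {"procedure": "TLM", "count": 4}, "sr": {"procedure": "TLM", "count": 4}},
      "observer2": {"sagittal": {"procedure": "AM", "count": 3}, "sr": {"procedure": "AM", "count": 4}}
    },
    {
      "case": 2,
      "gold": {"procedure": "TLM", "removals": {"intramural": 1, "subserosal": 0, "submucosal": 0}},
      "observer1": {"sagittal": {"procedure": "TLM", "count": 1}, "sr": {"procedure": "TLM", "count": 1}},
      "observer2": {"sagittal": {"procedure": "TCR", "count": 1}, "sr": {"procedure": "TLM", "count": 1}}
    },
    {
      "case": 3,
      "gold": {"procedure": "LAM", "removals": {"intramural": 1, "subserosal": 0, "submucosal": 0}},
      "observer1": {"sagittal": {"procedure": "TLM", "count": 1}, "sr": {"procedure": "TLM", "count": 1}},
      "observer2": {"sagittal": {"procedure": "AM", "count": 1}, "sr": {"procedure": "TLM", "count": 1}}
    },
    {
      "case": 4,
      "gold": {"procedure": "TLM", "removals": {"intramural": 2, "subserosal": 0, "submucosal": 0}},
      "observer1": {"sagittal": {"procedure": "TLM", "count": 2}, "sr": {"procedure": "TLM", "count": 2}},
      "observer2": {"sagittal": {"procedure": "TLM", "count": 2}, "sr": {"procedure": "TLM", "count": 2}}
    },
    {
      "case": 5,
      "gold": {"procedure": "TLM", "removals": {"intramural": 1, "subserosal": 0, "submucosal": 0}},
      "observer1": {"sagittal": {"procedure": "TLM", "count": 1}, "sr": {"procedure": "TLM", "count": 1}},
      "observer2": {"sagittal": {"procedure": "TLM", "count": 1}, "sr": {"procedure": "TCR", "count": 1}}
    },
    {
      "case": 6,
      "gold": {"procedure": "TLM", "removals": {"intramural": 1, "subserosal": 0, "submucosal": 0}},
      "observer1": {"sagittal": {"procedure": "TLM", "count": 1}, "sr": {"procedure": "TLM", "count": 1}},
      "observer2": {"sagittal": {"procedure": "TLM", "count": 1}, "sr": {"procedure": "TLM", "count": 1}}
    },
    {
      "case": 7,
      "gold": {"procedure": "TLM", "removals": {"intramural": 5, "subserosal": 1, "submucosal": 0}},
      "observer1": {"sagittal": {"procedure": "LAM", "count": 8}, "sr": {"procedure": "TLM", "count": 6}},
      "observer2": {"sagittal": {"procedure": "TLM", "count": 6}, "sr": {"procedure": "TLM", "count": 7}}
    },
    {
      "case": 8,
      "gold": {"procedure": "TLM", "removals": {"intramural": 5, "subserosal": 0, "submucosal": 0}},
      "observer1": {"sagittal": {"procedure": "LAM", "count": 9}, "sr": {"procedure": "LAM", "count": 6}},
      "observer2": {"sagittal": {"procedure": "TLM", "count": 7}, "sr": {"procedure": "TLM", "count": 6}}
    },
    {
      "case": 9,
      "gold": {"procedure": "TLM", "removals": {"intramural": 3, "subserosal": 0, "submucosal": 0}},
      "observer1": {"sagittal": {"procedure": "LAM", "count": 6}, "sr": {"procedure": "TLM", "count": 4}},
      "observer2": {"sagittal": {"procedure": "TLM", "count": 3}, "sr": {"procedure": "TLM", "count": 3}}
    },
    {
      "case": 10,
      "gold": {"procedure": "TCR", "removals": {"intramural": 0, "subserosal": 0, "submucosal": 1}},
      "observer1": {"sagittal": {"procedure": "TCR", "count": 1}, "sr": {"procedure": "TCR", "count": 1}},
      "observer2": {"sagittal": {"procedure": "TCR", "count": 2}, "sr": {"procedure": "TCR", "count": 1}}
    }
  ],
  "summaries": {
    "required_time_s": {
      "observer1": {
        "sagittal": {"mean": 19.7, "sd": 9.5, "n": 10},
        "sr": {"mean": 10.4, "sd": 5.1, "n": 10}
      },
      "observer2": {
        "sagittal": {"mean": 47.5, "sd": 12.3, "n": 10},
        "sr": {"mean": 19.7, "sd": 9.5, "n": 10}
      }
    },
    "difficulty_score": {
      "observer1": {
        "sagittal": {"mean": 1.6, "sd": 0.7, "n": 10},
        "sr": {"mean": 1.4, "sd": 0.7, "n": 10}
      },
      "observer2": {
        "sagittal": {"mean": 2.7, "sd": 0.7, "n": 10},
        "sr": {"mean": 2.4, "sd": 0.5, "n": 10}
      }
    }
  }
}
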