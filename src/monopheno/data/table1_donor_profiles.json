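{
  "description": "Published donor -> expression-profile assignments used for the donor-connectivity graph. Cluster rows list alternative profiles for some subpopulations ('20/22'); where the accompanying figure text fixes a donor's choice it is used (donors 3 and 14 carry OP-11, donor 20 OP-12, donors 13/18/19 no large-CD16neg profile, donor 22 OP-33, donors 23 and 25 OP-10, donors 17 and 25 OP-51); remaining alternatives are split round-robin among cluster members. Donors 7, 15 and 24 bridge clusters II and III with partial profiles; the other non-clustered donors carry single weakly-shared profiles.",
  "expected_clusters": {
    "I": [1, 2, 11, 12, 21],
    "II": [3, 13, 14, 18, 19, 20],
    "III": [4, 6, 10, 16, 17, 22, 23, 25],
    "IV": [5, 8]
  },
  "non_clustered": [7, 9, 15, 24, 26, 27, 28],
  "assignments": {
    "1":  ["OP-01", "OP-10", "OP-20", "OP-30", "OP-40", "OP-50"],
    "2":  ["OP-01", "OP-10", "OP-22", "OP-30", "OP-42", "OP-50"],
    "11": ["OP-01", "OP-10", "OP-20", "OP-30", "OP-40", "OP-50"],
    "12": ["OP-01", "OP-10", "OP-22", "OP-30", "OP-42", "OP-50"],
    "21": ["OP-01", "OP-10", "OP-20", "OP-30", "OP-40", "OP-50"],

    "3":  ["OP-04", "OP-11", "OP-20", "OP-32", "OP-41", "OP-51"],
    "13": ["OP-04", "OP-20", "OP-32", "OP-41", "OP-51"],
    "14": ["OP-04", "OP-11", "OP-20", "OP-32", "OP-41", "OP-51"],
    "18": ["OP-05", "OP-20", "OP-32", "OP-41", "OP-51"],
    "19": ["OP-05", "OP-20", "OP-32", "OP-41", "OP-51"],
    "20": ["OP-05", "OP-12", "OP-20", "OP-32", "OP-41", "OP-51"],

    "4":  ["OP-01", "OP-10", "OP-21", "OP-31", "OP-43"],
    "6":  ["OP-02", "OP-11", "OP-21", "OP-31", "OP-43"],
    "10": ["OP-01", "OP-11", "OP-21", "OP-33", "OP-44"],
    "16": ["OP-11", "OP-21", "OP-31", "OP-44"],
    "17": ["OP-11", "OP-21", "OP-31", "OP-43", "OP-51"],
    "22": ["OP-02", "OP-11", "OP-21", "OP-33", "OP-43"],
    "23": ["OP-10", "OP-21", "OP-31", "OP-44"],
    "25": ["OP-10", "OP-21", "OP-33", "OP-44", "OP-51"],

    "5":  ["OP-03", "OP-12"],
    "8":  ["OP-03", "OP-12"],

    "7":  ["OP-04", "OP-21"],
    "9":  ["OP-41"],
    "15": ["OP-05", "OP-21"],
    "24": ["OP-04", "OP-31"],
    "26": ["OP-33"],
    "27": ["OP-44"],
    "28": ["OP-05"]
  }
}
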