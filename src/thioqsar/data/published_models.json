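{
  "version": "1.0",
  "models": [
    {
      "model_id": 1,
      "response": "pKi_AChE",
      "intercept": 7.897,
      "terms": [
        ["fnotringSC7B", -0.214],
        ["fsp2Ssp3C7B", -0.271],
        ["notringC_Cl_8B", 0.249]
      ]
    },
    {
      "model_id": 2,
      "response": "pKi_BChE",
      "intercept": 6.565,
      "terms": [
        ["Cl_S_6B", 0.133],
        ["faccaroC6B", 0.036]
      ]
    },
    {
      "model_id": 3,
      "response": "pIC50_MAOA",
      "intercept": 6.898,
      "terms": [
        ["com_sp3C_6A", -0.034],
        ["Cl_notringC_6B", 0.052],
        ["fdonnotringC6B", -0.148]
      ]
    },
    {
      "model_id": 4,
      "response": "pIC50_MAOB",
      "intercept": 5.414,
      "terms": [
        ["com_Chyd_8A", 0.051],
        ["fOS7B", 0.473],
        ["C_sp3C_9B", -0.035]
      ]
    }
  ]
}
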