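{
  "agents": [
    {
      "name": "desflurane",
      "lambda_blood": 0.42,
      "lambda_vrg": 0.54,
      "lambda_mus": 0.97,
      "lambda_fat": 13.0,
      "mac": 6.0
    },
    {
      "name": "sevoflurane",
      "lambda_blood": 0.65,
      "lambda_vrg": 1.1,
      "lambda_mus": 2.4,
      "lambda_fat": 34.0,
      "mac": 2.0
    },
    {
      "name": "isoflurane",
      "lambda_blood": 1.3,
      "lambda_vrg": 2.1,
      "lambda_mus": 4.5,
      "lambda_fat": 70.0,
      "mac": 1.2
    }
  ],
  "body": {
    "weight": 70.0,
    "v_circuit": 8.0,
    "frc": 2.5,
    "q_total": 5.0,
    "v_vrg": 6.0,
    "v_mus": 33.0,
    "v_fat": 14.5,
    "f_vrg": 0.758,
    "f_mus": 0.18,
    "f_fat": 0.06
  },
  "overpressure_fd": {
    "desflurane": 18.0,
    "sevoflurane": 5.0,
    "isoflurane": 3.0
  }
}
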