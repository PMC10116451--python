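# Nanjing parameterization: 2019 graded-institution census per district,
# per-grade model coefficients, the 2035 horizon targets, and the
# smart-community cycle schedules.
grades:
  labels: [AAAAA, AAAA, AAA, AA, A]
  cost: [11250, 7200, 3600, 1875, 375]
  income: [7916, 5480, 2771.428571, 2333.333333, 750]
  beds: [777.6, 265.4, 168.1428571, 74.33333333, 35]
  min_share: [0.15, 0.15, 0.15, 0.15, 0.15]
horizon:
  cycles: 5
  population: 2560000
  bed_rate: 0.06
scenario:
  switch_cycle: 3
  income_factor: 0.5
  base_rate: 45
  increments: [3, 3, 4, 4, 4]
  reference_population: 2560000
districts:
  Xuanwu: [0, 2, 8, 2, 0]
  Qinhuai: [0, 6, 8, 7, 5]
  Gulou: [0, 7, 15, 3, 5]
  Liuhe: [0, 1, 3, 1, 1]
  Jianye: [1, 2, 4, 0, 2]
  Yuhuatai: [0, 2, 10, 2, 4]
  Qixia: [2, 4, 1, 9, 7]
  Pukou: [1, 1, 3, 6, 1]
  Jiangning: [2, 6, 8, 2, 8]
  Lishui: [0, 1, 4, 1, 1]
  Gaochun: [0, 1, 0, 0, 0]
schedules:
  original:
    base_rate: 45
    increments: [3, 3, 3, 3, 3]
  existing:
    base_rate: 45
    increments: [3, 3, 4, 4, 4]
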