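# Medical-care component of the Consumer Price Index, annual averages
# (approximate published values; replaceable config).  Costs in nominal
# dollars of the service year are converted to 2021 dollars by
# cost_2021 = cost_nominal * (index[2021] / index[year]).
medical_cpi:
  2014: 435.3
  2015: 446.8
  2016: 463.7
  2017: 475.3
  2018: 484.7
  2019: 498.2
  2020: 518.9
  2021: 521.5
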