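# Default codon table (version 1).
# Anchors: 002/003 = sphere size +/- feature pair; 230 = magnitude 100;
# 111 start, 333 stop; five part kinds each reachable via two codons.
version: 1
provenance: default
codons:
  "000": {category: 'feature', part: 'wire', property: 'weight', sign: '+'}
  "001": {category: 'part', part: 'joint'}
  "002": {category: 'feature', part: 'sphere', property: 'size', sign: '+'}
  "003": {category: 'feature', part: 'sphere', property: 'size', sign: '-'}
  "010": {category: 'part', part: 'sphere'}
  "011": {category: 'part', part: 'sphere'}
  "012": {category: 'feature', part: 'sphere', property: 'size', sign: '+'}
  "013": {category: 'feature', part: 'sphere', property: 'size', sign: '-'}
  "020": {category: 'feature', part: 'joint', property: 'motor_strength', sign: '+'}
  "021": {category: 'feature', part: 'joint', property: 'motor_strength', sign: '-'}
  "022": {category: 'feature', part: 'sphere', property: 'size', sign: '+'}
  "023": {category: 'feature', part: 'sphere', property: 'size', sign: '-'}
  "030": {category: 'feature', part: 'joint', property: 'motor_strength', sign: '+'}
  "031": {category: 'feature', part: 'joint', property: 'motor_strength', sign: '-'}
  "032": {category: 'feature', part: 'sphere', property: 'size', sign: '+'}
  "033": {category: 'feature', part: 'sphere', property: 'size', sign: '-'}
  "100": {category: 'feature', part: 'joint', property: 'motor_strength', sign: '+'}
  "101": {category: 'feature', part: 'joint', property: 'motor_strength', sign: '-'}
  "102": {category: 'part', part: 'sensor'}
  "103": {category: 'part', part: 'neuron'}
  "110": {category: 'part', part: 'joint'}
  "111": {category: 'start'}
  "112": {category: 'part', part: 'wire'}
  "113": {category: 'feature', part: 'wire', property: 'weight', sign: '-'}
  "120": {category: 'part', part: 'sensor'}
  "121": {category: 'part', part: 'wire'}
  "122": {category: 'feature', part: 'sphere', property: 'size', sign: '+'}
  "123": {category: 'feature', part: 'sphere', property: 'size', sign: '-'}
  "130": {category: 'part', part: 'neuron'}
  "131": {category: 'feature', part: 'sensor', property: 'gain', sign: '+'}
  "132": {category: 'feature', part: 'wire', property: 'weight', sign: '+'}
  "133": {category: 'feature', part: 'wire', property: 'weight', sign: '-'}
  "200": {category: 'feature', part: 'joint', property: 'motor_strength', sign: '+'}
  "201": {category: 'feature', part: 'joint', property: 'motor_strength', sign: '-'}
  "202": {category: 'feature', part: 'sensor', property: 'gain', sign: '+'}
  "203": {category: 'feature', part: 'sensor', property: 'gain', sign: '-'}
  "210": {category: 'feature', part: 'sensor', property: 'gain', sign: '+'}
  "211": {category: 'feature', part: 'sensor', property: 'gain', sign: '-'}
  "212": {category: 'feature', part: 'sensor', property: 'gain', sign: '+'}
  "213": {category: 'feature', part: 'sensor', property: 'gain', sign: '-'}
  "220": {category: 'magnitude', value: 20}
  "221": {category: 'magnitude', value: 40}
  "222": {category: 'magnitude', value: 50}
  "223": {category: 'magnitude', value: 25}
  "230": {category: 'magnitude', value: 100}
  "231": {category: 'magnitude', value: 80}
  "232": {category: 'magnitude', value: 10}
  "233": {category: 'magnitude', value: 5}
  "300": {category: 'feature', part: 'sensor', property: 'gain', sign: '+'}
  "301": {category: 'feature', part: 'sensor', property: 'gain', sign: '-'}
  "302": {category: 'feature', part: 'neuron', property: 'bias', sign: '+'}
  "303": {category: 'feature', part: 'neuron', property: 'bias', sign: '-'}
  "310": {category: 'feature', part: 'neuron', property: 'bias', sign: '+'}
  "311": {category: 'feature', part: 'neuron', property: 'bias', sign: '-'}
  "312": {category: 'feature', part: 'neuron', property: 'bias', sign: '+'}
  "313": {category: 'feature', part: 'neuron', property: 'bias', sign: '-'}
  "320": {category: 'feature', part: 'neuron', property: 'bias', sign: '+'}
  "321": {category: 'feature', part: 'neuron', property: 'bias', sign: '-'}
  "322": {category: 'feature', part: 'wire', property: 'weight', sign: '+'}
  "323": {category: 'feature', part: 'wire', property: 'weight', sign: '-'}
  "330": {category: 'feature', part: 'wire', property: 'weight', sign: '+'}
  "331": {category: 'feature', part: 'wire', property: 'weight', sign: '-'}
  "332": {category: 'feature', part: 'sensor', property: 'gain', sign: '-'}
  "333": {category: 'stop'}
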