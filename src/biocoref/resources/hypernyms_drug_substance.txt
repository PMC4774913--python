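# Hypernym headwords licensing nominal coreference to drug/substance entities.
drug
drugs
agent
agents
compound
compounds
solution
solutions
product
products
medication
medications
medicine
medicines
inhibitor
inhibitors
substance
substances
substrate
substrates
enzyme
enzymes
isoenzyme
isoenzymes
prodrug
prodrugs
glycoside
glycosides
anticoagulant
anticoagulants
diuretic
diuretics
class
classes
therapy
therapies
preparation
preparations
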