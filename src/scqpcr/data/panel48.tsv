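symbol	category	assay_id
Gapdh	housekeeping	Mm03302249_g1
Hprt	housekeeping	Mm03024075_m1
Rbfox3	neuronal_marker	Mm01248781_m1
Map2	neuronal_marker	Mm00485231_m1
Tubb3	neuronal_marker	Mm00727586_s1
Gfap	glial_marker	Mm01253033_m1
S100b	glial_marker	Mm00485897_m1
Hcrt	neuropeptide	Mm01964030_s1
Pmch	neuropeptide	Mm01242886_g1
Pdyn	neuropeptide	Mm00457573_m1
Gal	neuropeptide	Mm00439056_m1
Nts	neuropeptide	Mm00481140_m1
Nucb2	neuropeptide	Mm01137144_m1
Cartpt	neuropeptide	Mm04210469_m1
Trh	neuropeptide	Mm01182425_g1
Pnoc	neuropeptide	Mm01314909_m1
Crh	neuropeptide	Mm01293920_s1
Penk	neuropeptide	Mm01212875_m1
Tac1	neuropeptide	Mm01166996_m1
Tac2	neuropeptide	Mm01160362_m1
Sst	neuropeptide	Mm00436671_m1
Gad2	transmitter_component	Mm00484623_m1
Gad1	transmitter_component	Mm04207432_g1
Slc32a1	transmitter_component	Mm00494138_m1
Slc17a7	transmitter_component	Mm00436577_m1
Slc17a6	transmitter_component	Mm00499876_m1
Slc17a8	transmitter_component	Mm00805413_m1
Slc18a1	transmitter_component	Mm00461868_m1
Slc18a2	transmitter_component	Mm00553058_m1
Gls	transmitter_component	Mm01257297_m1
Chat	transmitter_component	Mm01221880_m1
Th	transmitter_component	Mm00447557_m1
Hdc	transmitter_component	Mm00456104_m1
Tph1	transmitter_component	Mm01202614_m1
Tph2	transmitter_component	Mm00557715_m1
Ada	other	Mm00545720_m1
Pvalb	calcium_binding	Mm00443100_m1
Calb2	calcium_binding	Mm00801461_m1
Calb1	calcium_binding	Mm00486647_m1
Nkx2.1	transcription_factor	Mm00447558_m1
Lhx9	transcription_factor	Mm00495308_m1
Nptx2	other	Mm00479438_m1
Igfbp3	other	Mm01187817_m1
Celf6	other	Mm01176134_m1
Nnat	other	Mm00731416_s1
Lepr	receptor	Mm00440181_m1
Ghsr	receptor	Mm00616415_m1
Mc4r	receptor	Mm00457483_s1
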