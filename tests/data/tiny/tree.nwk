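((BG006:0.240285,(BG005:0.224342,(MK1:0.015651,RL1:0.015651):0.073544):0.246516):0.060951,((BG003:0.210966,(BG007:0.162596,BG001:0.1427):0.25569):0.244596,(BG004:0.138631,(((MK2:0.024028,RL2:0.024028):0.10681,BG008:0.188646):0.256908,BG002:0.207916):0.292675):0.09866):0.088572):0.0;
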