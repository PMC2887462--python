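meta name ar

node MRSP 0.8
node ATP 0.7
node ADP 0.7
node ATPconsume 0.8
node ProtBiosynth 0.8
node ROS 0.1
node OXPROT 0.0
node NFkB 0.07
node MTOR 0.4
node Glycolysis 0.12

Reaction MRSP_ATP 0.8
pro ATP 5 5 5 5 5 0
sub ADP 0 5 5 5 5 5
act MRSP 0 1 2 3 4 5

Reaction ATP_used 1.05
sub ATP 0 1 2 3 4 5
pro ADP 5 5 5 5 5 2
act ATPconsume 0 1 2 3 4 5

Reaction Biosynth_consumed 0.092857
sub ATP 0 1 2 3 4 5
pro ADP 5 5 5 5 5 2
act ProtBiosynth 0 1 2 3 4 5

Reaction Biosynth_ATP 0.4
pro ProtBiosynth 5 5 5 5 5 0
act ATP 0 0 0 0 5 5

Reaction Biosynth_decay 0.25
sub ProtBiosynth 0 1 2 3 4 5

Reaction ATPconsume_ATP 0.3
pro ATPconsume 5 5 5 5 5 0
act ATP 0 0 0 2 5 5

Reaction ATPconsume_decay 0.2625
sub ATPconsume 0 1 2 3 4 5

Reaction MRSP_ADP 0.1333333
pro MRSP 5 5 5 5 5 0
act ADP 0 1 2 3 3 3

Reaction MRSP_turnover 0.1
sub MRSP 0 1 2 3 4 5

Reaction MRSP_deactivation 0.3
sub MRSP 0 1 2 3 4 5
act ROS 0 1 2 3 4 5

Reaction MRSP_ROS 0.1
pro ROS 5 5 5 5 5 0
act MRSP 0 1 2 3 4 5

Reaction ROS_amplification 1.8
pro ROS 5 5 5 5 5 0
act ROS 1 2 3 4 5 5
act OXPROT 0 1 2 3 4 5

Reaction ROS_scavenged 0.8
sub ROS 0 1 2 3 4 5

Reaction ROS_OXPROT 0.3
pro OXPROT 5 5 5 5 5 0
act ROS 0 1 2 3 4 5

Reaction Biosynth_ROS 0.05
sub ProtBiosynth 0 1 2 3 4 5
act ROS 0 1 2 3 4 5

Reaction Autophagy_MTOR 0.05
sub OXPROT 1 2 3 4 5 5
act MTOR 5 2 1 0 0 0

Reaction NFkB_ROS 0.2333333
pro NFkB 5 5 5 5 5 0
act ROS 0 3 5 5 5 5

Reaction NFkB_OXPROT 0.45
pro NFkB 5 5 5 5 5 0
act OXPROT 0 2 3 4 5 5

Reaction NFkB_decay 1.0
sub NFkB 0 1 2 3 4 5

Reaction Scavenge_NFkB 1.0
sub ROS 0 1 2 3 4 5
act NFkB 0 1 2 3 4 5

Reaction MRSP_NFkB 0.25
sub MRSP 2 3 4 4 5 5
act NFkB 0 1 2 3 4 5

Reaction NADPH_NFkB 0.19
pro ROS 5 5 5 5 5 0
act NFkB 0 1 2 3 4 5

Reaction Glycolysis_NFkB 0.3
pro Glycolysis 5 5 5 5 5 0
act NFkB 0 1 2 3 4 5

Reaction MTOR_basal 0.48
pro MTOR 5 5 5 5 5 0

Reaction MTOR_ATP 2.0
sub MTOR 0 1 2 3 4 5
act ATP 5 5 5 5 1 1

Reaction MTOR_ROS 0.15
pro MTOR 5 5 5 5 5 0
act ROS 0 0 2 4 5 5

Reaction Biosynth_MTOR 0.03
pro ProtBiosynth 5 5 5 5 5 0
act MTOR 0 1 2 3 4 5
act ATP 0 1 2 3 4 5

Reaction MRSP_MTOR 0.04
pro MRSP 5 5 5 5 5 0
act MTOR 0 1 2 3 4 5

Reaction Glycolysis_MTOR 0.05
pro Glycolysis 5 5 5 5 5 0
act MTOR 0 0 1 3 5 5

Reaction Glycolysis_decay 0.25
sub Glycolysis 0 1 2 3 4 5

Reaction Glyc_ATP 0.02
pro ATP 5 5 5 5 5 0
sub ADP 0 5 5 5 5 5
act Glycolysis 0 1 2 3 4 5

Reaction Turnover_OXPROT 0.05
pro OXPROT 5 5 5 5 5 0
act ProtBiosynth 5 4 3 2 1 0

Reaction Proteolysis_MTOR 0.217
sub OXPROT 0 5 3 2 2 2
act MTOR 5 2 1 0 0 0

Reaction Autophagy_ATP 0.05
sub OXPROT 0 5 3 2 2 2
act ATP 0 1 2 3 4 5

Reaction ATPconsume_MTOR 0.01
pro ATPconsume 5 5 5 5 5 0
act MTOR 0 1 2 3 4 5

Reaction ATPconsume_Glycolysis 0.01
pro ATPconsume 5 5 5 5 5 0
act Glycolysis 0 2 3 4 5 5
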